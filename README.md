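# actinfsim

A discrete-state active-inference agent for simulating adaptive and
stress-lesioned defensive behaviour. A small foraging agent lives in a
world with three hidden-state factors (nearby creatures, self-motion,
heart rate) and three sensory modalities (audition, vision, joint
proprio-/baroreception). It estimates hidden states by variational
message passing, scores seven fixed action policies by expected free
energy (risk + ambiguity), and selects actions from the softmax policy
posterior. A single-parameter "lesion" — sharpening the prior aversion
to the predator's visual form from −6.25 to −10 — together with a
safe/unsafe contextual prior yields four agent variants whose policy
selection statistics reproduce hyperarousal- and hypervigilance-like
phenotypes, including an approximately 4-fold increase in unrelenting
("hard") freezing for the lesioned agent under an unsafe prior.

## Layout

| module | contents |
| --- | --- |
| `actinfsim.model_spec` | typed containers (A/B/C/D/E/U arrays), validators, default intact/lesioned safe/unsafe model builders, YAML serialization |
| `actinfsim.inference_engine` | per-policy state posteriors by damped fixed-point message passing; variational free energy |
| `actinfsim.policy_engine` | expected free energy (risk/ambiguity decomposition), policy posterior, action selection |
| `actinfsim.world` | the true environment (shares the model's kernels), scenario openings, scripted-trajectory overrides |
| `actinfsim.neural_responses` | synthetic local field potentials from belief-update rates of change |
| `actinfsim.experiments` | trial loop, variant × condition × n-trial grids, phenotype metrics with bootstrap intervals |
| `actinfsim.cli_io` / `actinfsim.cli` | schema-validated configs, deterministic CSV/JSON writers, `actinfsim` command |

Two ready-made model documents ship with the package
(`actinfsim/models/intact.yaml`, `lesioned.yaml`).

## CLI

```sh
actinfsim validate                       # check the default model
actinfsim simulate  --scenario scenario1 --condition b --seed 1 --out out/
actinfsim experiment --scenario scenario2 --all-cells --n-trials 32 --out out/
actinfsim summarize --selections out/selections/table.csv --out out/
```

All commands accept `--config PATH` (YAML/JSON; unknown keys rejected;
empty file = defaults) and echo the effective configuration beside their
outputs. `simulate` writes the trial trace (states, outcomes, actions,
per-policy free energies, beliefs, LFP raster); `experiment` writes
per-trial policy selections and a policy × cell counts table;
`summarize` computes defensive frequencies, hard-freeze fold changes
and relaxed-resumption contrasts with bootstrap percentile intervals.

## Notes

- Unspecified transition probabilities (creature attraction, evasion,
  wandering, spurious sounds) are exposed as `ModelConfig` free
  parameters; the defaults were chosen so the four variants reproduce
  the qualitative phenotype contrasts. Substituting other values
  requires no code changes (`model:` section of the run config).
- Zero probabilities are floored at `exp(-16)` inside the inference
  engine (configurable; `floor=0` gives exact arithmetic and `+inf`
  free-energy sentinels for impossible observations).
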