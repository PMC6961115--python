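"""Synthetic local field potentials from belief-update dynamics.

Posterior beliefs are read as neuronal firing rates; their first
differences across variational iterates yield depolarisation-like
deflections.  One "unit" is a (factor, level, epoch-belief) triple; the
raster stacks each unit's difference series over the whole trial, and a
rectified per-iterate sum provides an aggregate amplitude series.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LfpTrace", "simulate_lfp", "DEFAULT_DT"]

#: 250 ms per epoch / 16 logged iterates.
DEFAULT_DT = 0.25 / 16.0


@dataclass
class LfpTrace:
    """raster: (n_units, n_iterates - 1) signed first differences.

    aggregate is the per-iterate column sum of the raster; amplitude is
    the rectified column sum (used for event detection, since the signed
    sum of a probability simplex's differences vanishes by construction).
    """

    raster: np.ndarray
    aggregate: np.ndarray
    amplitude: np.ndarray
    time_axis: np.ndarray
    unit_labels: list[str]
    iterates_per_epoch: int

    @property
    def n_units(self) -> int:
        return self.raster.shape[0]

    def epoch_of_iterate(self, i: int) -> int:
        """1-based epoch of difference sample i (0-based).

        Sample i sits between iterates i and i+1; a sample on a slab
        boundary belongs to the incoming epoch, whose observation drives
        the belief change it records.
        """
        return (int(i) + 1) // self.iterates_per_epoch + 1

    def peak_epoch(self) -> int:
        """1-based epoch containing the maximum aggregate amplitude."""
        return self.epoch_of_iterate(int(np.argmax(self.amplitude)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for u, label in enumerate(self.unit_labels):
            rows.append(
                pd.DataFrame(
                    {
                        "iterate": np.arange(1, self.raster.shape[1] + 1),
                        "time_s": self.time_axis,
                        "unit": label,
                        "value": self.raster[u],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def simulate_lfp(
    belief_iterates: np.ndarray,
    dt: float = DEFAULT_DT,
    *,
    unit_labels: list[str] | None = None,
    iterates_per_epoch: int = 16,
    smooth: int = 0,
) -> LfpTrace:
    """Turn a (n_iterates, n_units) belief raster into an LFP trace.

    ``belief_iterates`` concatenates, over epochs, the logged variational
    iterates of the (policy-averaged) state posteriors; n_iterates is
    horizon * iterates_per_epoch.  ``smooth`` > 1 applies a moving
    average of that window to the raster (off by default).
    """
    X = np.asarray(belief_iterates, dtype=float)
    if X.ndim != 2:
        raise ValueError("belief_iterates must be 2-D (iterates, units)")
    diffs = np.diff(X, axis=0).T  # (units, iterates-1)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        diffs = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="same"), 1, diffs
        )
    aggregate = diffs.sum(axis=0)
    amplitude = np.abs(diffs).sum(axis=0)
    time_axis = (np.arange(diffs.shape[1]) + 1) * dt
    if unit_labels is None:
        unit_labels = [f"unit{u}" for u in range(diffs.shape[0])]
    return LfpTrace(
        raster=diffs,
        aggregate=aggregate,
        amplitude=amplitude,
        time_axis=time_axis,
        unit_labels=list(unit_labels),
        iterates_per_epoch=iterates_per_epoch,
    )
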