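"""Powder averaging: collapse per-direction signals to one value per shell.

Averaging the signal arithmetically over the encoding directions of a shell
yields a rotation-invariant quantity that no longer depends on the voxel's
orientation distribution — the input the gamma model is fitted to. The mean
is the plain arithmetic mean (no noise-floor or magnitude-bias correction);
shell membership is an exact match on (b, b_delta) after rounding to 1e-6,
so jittered b-values must be pre-binned by the reader.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .encoding import EncodingScheme

__all__ = ["PowderShells", "powder_average"]


class PowderShells:
    """Direction-averaged signal per (b, b_delta) shell.

    Thin wrapper around a tidy DataFrame with columns
    ``b, b_delta, mean_signal, n_directions, signal_sd``, ordered by
    ascending (b_delta, b).
    """

    COLUMNS = ["b", "b_delta", "mean_signal", "n_directions", "signal_sd"]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"missing shell columns: {sorted(missing)}")
        table = table[self.COLUMNS].copy()
        if table.duplicated(subset=["b", "b_delta"]).any():
            raise ValueError("one row per distinct (b, b_delta) required")
        if (table["mean_signal"] < 0).any():
            raise ValueError("mean_signal must be non-negative")
        if (table["n_directions"] < 1).any():
            raise ValueError("n_directions must be >= 1")
        self.table = table.sort_values(["b_delta", "b"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def b(self) -> np.ndarray:
        return self.table["b"].to_numpy()

    @property
    def b_delta(self) -> np.ndarray:
        return self.table["b_delta"].to_numpy()

    @property
    def mean_signal(self) -> np.ndarray:
        return self.table["mean_signal"].to_numpy()

    def select(self, b_delta: float, atol: float = 1e-6) -> "PowderShells":
        """Shells of a single b-tensor shape."""
        m = np.abs(self.table["b_delta"] - b_delta) < atol
        return PowderShells(self.table[m])

    def to_csv(self, path) -> None:
        out = self.table.rename(columns={"n_directions": "n", "signal_sd": "sd"})
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PowderShells":
        df = pd.read_csv(path).rename(columns={"n": "n_directions", "sd": "signal_sd"})
        return cls(df)

    @classmethod
    def from_arrays(cls, b, b_delta, mean_signal, n_directions=None, signal_sd=None) -> "PowderShells":
        b = np.asarray(b, dtype=float)
        n = np.ones_like(b, dtype=int) if n_directions is None else np.asarray(n_directions)
        sd = np.zeros_like(b) if signal_sd is None else np.asarray(signal_sd, dtype=float)
        return cls(
            pd.DataFrame(
                {
                    "b": b,
                    "b_delta": np.broadcast_to(np.asarray(b_delta, dtype=float), b.shape),
                    "mean_signal": np.asarray(mean_signal, dtype=float),
                    "n_directions": n,
                    "signal_sd": sd,
                }
            )
        )


def powder_average(signals, scheme: EncodingScheme) -> PowderShells:
    """Arithmetic mean (and sample SD) of the signal within each shell."""
    signals = np.asarray(signals, dtype=float)
    if signals.shape != (len(scheme),):
        raise ValueError(
            f"signals ({signals.shape}) must align 1:1 with scheme entries ({len(scheme)})"
        )
    rows = []
    for b, bd, idx in scheme.shells():
        vals = signals[idx]
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append((b, bd, float(np.mean(vals)), len(vals), sd))
    return PowderShells(pd.DataFrame(rows, columns=PowderShells.COLUMNS))
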