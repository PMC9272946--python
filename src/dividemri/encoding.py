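"""b-tensor acquisition schemes for tensor-valued diffusion encoding.

An acquisition is abstracted to one :class:`EncodingEntry` per image volume:
a b-value ``b`` (ms/um^2), a b-tensor shape ``b_delta`` (1 for linear tensor
encoding, LTE; 0 for spherical tensor encoding, STE) and the symmetry axis of
the b-tensor. The axisymmetric b-tensor implied by an entry is

    B = b * [ (1 - b_delta)/3 * I + b_delta * n n^T ]

so that trace(B) = b and b_delta interpolates between spherical (b_delta = 0)
and rank-1 linear (b_delta = 1) encoding; b_delta = -0.5 is planar.

Units are fixed: b in ms/um^2, diffusivities in um^2/ms. Scheme files that
declare ``b_units=s/mm2`` are converted on read (x 1e-3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EncodingEntry",
    "EncodingScheme",
    "build_protocol",
    "btensor_of",
    "directions",
    "read_scheme",
    "write_scheme",
    "ELECTROSTATIC_8",
]

#: Antipodally symmetric electrostatic-repulsion optimum for 8 directions
#: (minimum of sum 1/d^2 over both antipodal pair distances; minimum pairwise
#: angle 44.8 deg). Frozen so the default protocol is reproducible.
ELECTROSTATIC_8 = np.array(
    [
        [-0.2089323505988418, -0.9744723097211867, 0.0821644111516540],
        [0.8410263299430334, 0.5116280112129155, 0.1758166388168902],
        [-0.8418714456723030, 0.4662294101172278, 0.2718135502570987],
        [0.4510527310170236, -0.7681211011169918, 0.4544682693664152],
        [-0.7129256098907691, -0.3303256152172526, 0.6185645178097580],
        [0.7129062798721276, -0.0257732663621753, 0.7007855412748667],
        [-0.0752462365716569, 0.7059265087037387, 0.7042767695949885],
        [-0.0529441450875281, -0.1239706543430285, 0.9908724410148423],
    ]
)

_SHELL_DECIMALS = 6  # shells are exact matches on (b, b_delta) after rounding


def _shell_key(b: float, b_delta: float) -> tuple[float, float]:
    return (round(float(b), _SHELL_DECIMALS), round(float(b_delta), _SHELL_DECIMALS))


@dataclass(frozen=True)
class EncodingEntry:
    """One diffusion-encoded volume: (b, b_delta, symmetry axis)."""

    b: float
    b_delta: float
    direction: np.ndarray

    def __post_init__(self):
        if self.b < 0:
            raise ValueError(f"b-value must be non-negative, got {self.b}")
        if not (-0.5 <= self.b_delta <= 1.0):
            raise ValueError(
                f"b_delta must lie in [-0.5, 1], got {self.b_delta}"
            )
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,):
            raise ValueError("direction must be a 3-vector")
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError(f"direction must be a unit vector, |n| = {np.linalg.norm(d)}")
        object.__setattr__(self, "direction", d)

    @property
    def btensor(self) -> np.ndarray:
        return btensor_of(self)


def btensor_of(entry: EncodingEntry) -> np.ndarray:
    """Symmetric 3x3 b-tensor of an entry, trace equal to its b-value."""
    n = entry.direction
    return entry.b * (
        (1.0 - entry.b_delta) / 3.0 * np.eye(3) + entry.b_delta * np.outer(n, n)
    )


class EncodingScheme:
    """Ordered collection of encoding entries, partitioned into shells.

    A shell is the set of entries sharing one (b, b_delta) pair; shells are
    the unit over which signals are powder-averaged downstream.
    """

    def __init__(self, entries: list[EncodingEntry]):
        if not entries:
            raise ValueError("scheme must contain at least one entry")
        self.entries = list(entries)
        self._shells: dict[tuple[float, float], list[int]] = {}
        for i, e in enumerate(self.entries):
            self._shells.setdefault(_shell_key(e.b, e.b_delta), []).append(i)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def b(self) -> np.ndarray:
        return np.array([e.b for e in self.entries])

    @property
    def b_delta(self) -> np.ndarray:
        return np.array([e.b_delta for e in self.entries])

    @property
    def directions(self) -> np.ndarray:
        return np.array([e.direction for e in self.entries])

    @property
    def btensors(self) -> np.ndarray:
        """(n, 3, 3) stack of b-tensors."""
        return np.array([btensor_of(e) for e in self.entries])

    @property
    def shell_index(self) -> dict[tuple[float, float], list[int]]:
        """Mapping (b, b_delta) -> entry indices, keys rounded to 1e-6."""
        return {k: list(v) for k, v in self._shells.items()}

    @property
    def n_shells(self) -> int:
        return len(self._shells)

    def shells(self) -> list[tuple[float, float, list[int]]]:
        """Shells in ascending (b_delta, b) order."""
        keys = sorted(self._shells, key=lambda k: (k[1], k[0]))
        return [(b, bd, list(self._shells[(b, bd)])) for b, bd in keys]


def directions(n: int, strategy: str = "auto") -> np.ndarray:
    """Deterministic direction set of ``n`` unit vectors on the half-sphere.

    ``"electrostatic"`` uses the frozen 8-point repulsion optimum (n must be
    8); ``"fibonacci"`` spreads any n by the spherical Fibonacci lattice;
    ``"auto"`` picks electrostatic for n = 8, Fibonacci otherwise.
    """
    if n < 1:
        raise ValueError("n_directions must be >= 1")
    if strategy == "auto":
        strategy = "electrostatic" if n == 8 else "fibonacci"
    if strategy == "electrostatic":
        if n != 8:
            raise ValueError("the electrostatic set is precomputed for n = 8 only")
        return ELECTROSTATIC_8.copy()
    if strategy == "fibonacci":
        i = np.arange(n)
        # half-sphere: z from ~0 to ~1, golden-angle azimuth
        z = (i + 0.5) / n
        phi = i * np.pi * (3.0 - np.sqrt(5.0))
        r = np.sqrt(1.0 - z**2)
        return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    raise ValueError(f"unknown direction strategy: {strategy!r}")


def build_protocol(
    b_values,
    shapes=(1.0, 0.0),
    n_directions: int = 8,
    direction_set="auto",
) -> EncodingScheme:
    """Construct a multi-shell scheme: one shell per (b, shape) pair.

    Parameters
    ----------
    b_values : sequence of float
        Shell b-values in ms/um^2, all >= 0.
    shapes : sequence of float
        b-tensor shapes, each in [-0.5, 1] (1 = LTE, 0 = STE).
    n_directions : int
        Encoding directions per shell. The same direction table is reused
        across shells.
    direction_set : str or (n, 3) array
        Named strategy passed to :func:`directions`, or an explicit table of
        unit vectors with ``n_directions`` rows.
    """
    b_values = [float(b) for b in b_values]
    if not b_values:
        raise ValueError("b_values must be nonempty")
    if any(b < 0 for b in b_values):
        raise ValueError("b-values must be non-negative")
    for s in shapes:
        if not (-0.5 <= s <= 1.0):
            raise ValueError(f"b_delta must lie in [-0.5, 1], got {s}")
    if isinstance(direction_set, str):
        dirs = directions(n_directions, direction_set)
    else:
        dirs = np.asarray(direction_set, dtype=float)
        if dirs.shape != (n_directions, 3):
            raise ValueError(
                f"direction table must have shape ({n_directions}, 3), got {dirs.shape}"
            )
    entries = [
        EncodingEntry(b, float(s), d)
        for s in shapes
        for b in b_values
        for d in dirs
    ]
    return EncodingScheme(entries)


# ---------------------------------------------------------------------------
# Scheme file I/O: whitespace-delimited text, `b b_delta nx ny nz`, with a
# `#`-header declaring b units.

def write_scheme(scheme: EncodingScheme, path) -> None:
    lines = ["# b_units=ms/um2"]
    for e in scheme.entries:
        lines.append(
            "%.17g %.17g %.17g %.17g %.17g"
            % (e.b, e.b_delta, e.direction[0], e.direction[1], e.direction[2])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_scheme(path) -> EncodingScheme:
    scale = 1.0
    entries = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            decl = line.lstrip("#").strip()
            if decl.startswith("b_units="):
                unit = decl.split("=", 1)[1].strip()
                if unit in ("ms/um2", "ms/μm2"):
                    scale = 1.0
                elif unit == "s/mm2":
                    scale = 1e-3
                else:
                    raise ValueError(f"unknown b units: {unit!r}")
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"scheme row must have 5 columns: {line!r}")
        b, bd, nx, ny, nz = map(float, parts)
        d = np.array([nx, ny, nz])
        nrm = np.linalg.norm(d)
        if nrm == 0:
            d = np.array([0.0, 0.0, 1.0])
        elif abs(nrm - 1.0) > 1e-9:  # normalize sloppy files, keep exact ones bit-identical
            d = d / nrm
        entries.append(EncodingEntry(b * scale, bd, d))
    return EncodingScheme(entries)
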