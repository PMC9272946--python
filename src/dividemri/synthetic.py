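"""Synthetic multi-Gaussian diffusion data with known ground truth.

A voxel is modelled as a finite mixture of axisymmetric Gaussian diffusion
micro-environments (a diffusion tensor distribution, DTD). Each component
with tensor D attenuates as exp(-B : D) under b-tensor B, so the voxel signal
is

    S = S0 * sum_i f_i * exp(-B : D_i).

Ground-truth summary parameters follow from the moments of the DTD:

    MD   = E_f[D_iso],            D_iso = (lambda_par + 2 lambda_perp) / 3
    MK_I = 3 Var_f(D_iso) / MD^2
    MK_A = 3 V_A / MD^2,          V_A = (4/45) E_f[(lambda_par - lambda_perp)^2]

V_A is the extra variance of the apparent diffusivity seen by linear encoding
after averaging over uniformly distributed encoding directions: for one
axisymmetric tensor, D(theta) = lambda_perp + (lambda_par - lambda_perp)
cos^2(theta) and Var(cos^2 theta) = 4/45 on the sphere. These coefficients
are cross-checked in the test suite against a numeric low-b cumulant fit of
exactly powder-averaged signals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import special

from .encoding import EncodingScheme

__all__ = [
    "MicroTensor",
    "TensorDistribution",
    "GroundTruth",
    "PhantomSpec",
    "Phantom",
    "sphere_points",
    "simulate_signal",
    "powder_signal",
    "dtd_moments",
    "add_rician_noise",
    "add_gaussian_noise",
    "make_phantom",
    "phantom_rois",
    "DEFAULT_CLASS_RANGES",
]


@dataclass(frozen=True)
class MicroTensor:
    """Axisymmetric Gaussian micro-environment."""

    lambda_par: float
    lambda_perp: float
    orientation: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        if self.lambda_par < 0 or self.lambda_perp < 0:
            raise ValueError("diffusivities must be non-negative")
        u = np.asarray(self.orientation, dtype=float)
        if u.shape != (3,) or abs(np.linalg.norm(u) - 1.0) > 1e-9:
            raise ValueError("orientation must be a unit 3-vector")
        object.__setattr__(self, "orientation", u)

    @property
    def diso(self) -> float:
        """Isotropic (mean) diffusivity of the component, um^2/ms."""
        return (self.lambda_par + 2.0 * self.lambda_perp) / 3.0

    @property
    def delta(self) -> float:
        """Axial minus radial diffusivity, um^2/ms."""
        return self.lambda_par - self.lambda_perp

    def tensor(self) -> np.ndarray:
        u = self.orientation
        return self.lambda_perp * np.eye(3) + self.delta * np.outer(u, u)


class TensorDistribution:
    """Finite mixture of :class:`MicroTensor` components with weights."""

    def __init__(self, components):
        components = list(components)
        if not components:
            raise ValueError("tensor distribution must have at least one component")
        self.weights = np.array([float(w) for w, _ in components])
        self.tensors = [t for _, t in components]
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {self.weights.sum()}")

    def __len__(self):
        return len(self.tensors)

    @property
    def diso(self) -> np.ndarray:
        return np.array([t.diso for t in self.tensors])

    @property
    def delta(self) -> np.ndarray:
        return np.array([t.delta for t in self.tensors])

    def dtensors(self) -> np.ndarray:
        """(m, 3, 3) stack of component diffusion tensors."""
        return np.array([t.tensor() for t in self.tensors])

    # -- constructors -------------------------------------------------------

    @classmethod
    def isotropic_mixture(cls, disos, weights=None) -> "TensorDistribution":
        disos = list(disos)
        if weights is None:
            weights = [1.0 / len(disos)] * len(disos)
        return cls(
            [(w, MicroTensor(d, d)) for w, d in zip(weights, disos)]
        )

    @classmethod
    def randomly_oriented(
        cls,
        lambda_par: float,
        lambda_perp: float,
        n_orientations: int = 256,
        rng=None,
    ) -> "TensorDistribution":
        """One micro-tensor replicated over quasi-uniform orientations.

        Realizes "anisotropic but randomly ordered" micro-environments by
        component expansion: ``n_orientations`` equal-weight copies on a
        low-discrepancy spherical lattice (seed-jittered when ``rng`` given),
        keeping the forward model strictly multi-Gaussian.
        """
        dirs = sphere_points(n_orientations, rng=rng)
        w = 1.0 / n_orientations
        return cls([(w, MicroTensor(lambda_par, lambda_perp, u)) for u in dirs])

    @classmethod
    def from_moment_targets(
        cls,
        md: float,
        mk_i: float,
        mk_a: float,
        n_orientations: int = 256,
        n_iso: int = 16,
        rng=None,
    ) -> "TensorDistribution":
        """Tissue-like mixture with moments at (or very near) the targets.

        Half the weight is an isotropic sub-population whose diffusivities
        follow a discretized gamma distribution (mean MD, variance set by the
        MK_I target) — a smooth unimodal spread of diffusivities rather than
        an extreme two-point split. The other half is one axisymmetric tensor
        with mean diffusivity MD, replicated over quasi-uniform orientations,
        whose anisotropy is set by the MK_A target. Clipping at zero can
        perturb the moments marginally; read the exact values back with
        :func:`dtd_moments`.

        Raises if the MK_A target would need a negative radial diffusivity.
        """
        if md <= 0:
            raise ValueError("MD must be positive")
        v_i = mk_i * md**2 / 3.0
        v_a = mk_a * md**2 / 3.0
        w_iso = 0.5
        var_iso = v_i / w_iso  # variance of the isotropic sub-population
        if var_iso > 0:
            from scipy import stats as _sps

            q = (np.arange(n_iso) + 0.5) / n_iso
            levels = _sps.gamma.ppf(q, md**2 / var_iso, scale=var_iso / md)
            sd = levels.std()
            if sd > 0:  # rescale the discretization to the exact variance
                levels = md + (levels - levels.mean()) * (np.sqrt(var_iso) / sd)
            levels = np.clip(levels, 1e-3 * md, None)
        else:
            levels = np.full(n_iso, md)
        comps = [(w_iso / n_iso, MicroTensor(d, d)) for d in levels]
        delta = np.sqrt(v_a / ((1.0 - w_iso) * 4.0 / 45.0))
        lam_perp = md - delta / 3.0
        lam_par = lam_perp + delta
        if lam_perp < 0:
            raise ValueError("MK_A target needs a negative radial diffusivity")
        dirs = sphere_points(n_orientations, rng=rng)
        w = (1.0 - w_iso) / n_orientations
        comps += [(w, MicroTensor(lam_par, lam_perp, u)) for u in dirs]
        return cls(comps)


@dataclass(frozen=True)
class GroundTruth:
    """Oracle (MD, MK_I, MK_A) of a tensor distribution."""

    md: float
    mk_i: float
    mk_a: float


def sphere_points(n: int, rng=None) -> np.ndarray:
    """Quasi-uniform points on the full sphere (Fibonacci lattice).

    With ``rng`` given, applies a small seed-controlled jitter to azimuth and
    latitude so repeated draws are decorrelated but reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n)
    if rng is None:
        off_z, off_p = 0.0, 0.0
    else:
        off_z = rng.uniform(-0.5 / n, 0.5 / n)
        off_p = rng.uniform(0, 2 * np.pi)
    z = np.clip(-1.0 + (2.0 * i + 1.0) / n + off_z, -1.0, 1.0)
    phi = i * np.pi * (3.0 - np.sqrt(5.0)) + off_p
    r = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


# ---------------------------------------------------------------------------
# Forward model

def simulate_signal(dtd: TensorDistribution, scheme: EncodingScheme, s0: float = 1.0) -> np.ndarray:
    """Per-entry multi-Gaussian signal ``s0 * sum_i f_i exp(-B_k : D_i)``."""
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    B = scheme.btensors  # (n, 3, 3)
    D = dtd.dtensors()  # (m, 3, 3)
    bd = np.einsum("kab,iab->ki", B, D)
    return s0 * (np.exp(-bd) @ dtd.weights)


def _mean_exp_quad(a):
    """E[exp(-a t^2)] with t uniform on [0, 1] (orientation average kernel).

    Equals sqrt(pi) erf(sqrt(a)) / (2 sqrt(a)) for a > 0 and the erfi analog
    for a < 0; near zero a series avoids 0/0.
    """
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    small = np.abs(a) < 1e-8
    # series: 1 - a/3 + a^2/10 - a^3/42
    s = a[small]
    out[small] = 1.0 - s / 3.0 + s**2 / 10.0 - s**3 / 42.0
    pos = (~small) & (a > 0)
    neg = (~small) & (a < 0)
    ra = np.sqrt(a[pos])
    out[pos] = np.sqrt(np.pi) * special.erf(ra) / (2.0 * ra)
    rb = np.sqrt(-a[neg])
    out[neg] = np.sqrt(np.pi) * special.erfi(rb) / (2.0 * rb)
    return out


def powder_signal(dtd: TensorDistribution, b, b_delta, s0: float = 1.0) -> np.ndarray:
    """Exactly powder-averaged signal per (b, b_delta).

    Averages exp(-B : D) analytically over encoding directions uniform on the
    sphere. For axisymmetric B (axis n) and D (axis u),
    B : D = b [(1 - b_delta) D_iso + b_delta (lambda_perp + delta (n.u)^2)],
    and (n.u)^2 averages via :func:`_mean_exp_quad`. Used for ideal
    signal-versus-b curves and as the reference in cumulant checks; acquired
    data is instead powder-averaged over the finite direction set.
    """
    b = np.atleast_1d(np.asarray(b, dtype=float))
    bd = np.broadcast_to(np.asarray(b_delta, dtype=float), b.shape)
    diso = dtd.diso
    lperp = np.array([t.lambda_perp for t in dtd.tensors])
    delta = dtd.delta
    # (k, i) exponent pieces
    base = b[:, None] * ((1.0 - bd[:, None]) * diso[None, :] + bd[:, None] * lperp[None, :])
    a = b[:, None] * bd[:, None] * delta[None, :]
    sig = np.exp(-base) * _mean_exp_quad(a)
    return s0 * (sig @ dtd.weights)


def dtd_moments(dtd: TensorDistribution) -> GroundTruth:
    """Ground-truth (MD, MK_I, MK_A) from the mixture moments."""
    f = dtd.weights
    diso = dtd.diso
    md = float(f @ diso)
    var_iso = float(f @ (diso - md) ** 2)
    v_a = float(4.0 / 45.0 * (f @ dtd.delta**2))
    if md == 0.0:
        if var_iso > 0 or v_a > 0:
            raise ZeroDivisionError(
                "kurtosis undefined: MD = 0 with nonzero diffusivity variance"
            )
        return GroundTruth(0.0, 0.0, 0.0)
    return GroundTruth(md, 3.0 * var_iso / md**2, 3.0 * v_a / md**2)


# ---------------------------------------------------------------------------
# Noise

def add_rician_noise(signals, sigma: float, rng=None) -> np.ndarray:
    """Magnitude-MRI (Rician) noise: |s + g1 + i g2| with g ~ N(0, sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signals = np.asarray(signals, dtype=float)
    if sigma == 0:
        return signals.copy()
    rng = np.random.default_rng(rng)
    g1 = rng.normal(0.0, sigma, size=signals.shape)
    g2 = rng.normal(0.0, sigma, size=signals.shape)
    return np.sqrt((signals + g1) ** 2 + g2**2)


def add_gaussian_noise(signals, sigma: float, rng=None) -> np.ndarray:
    """Additive Gaussian option for cumulant-regime tests."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signals = np.asarray(signals, dtype=float)
    if sigma == 0:
        return signals.copy()
    rng = np.random.default_rng(rng)
    return signals + rng.normal(0.0, sigma, size=signals.shape)


# ---------------------------------------------------------------------------
# Digital prostate-like phantom

#: Per-class (MD um^2/ms, MK_I, MK_A) ranges chosen to reproduce the
#: qualitative contrasts of prostate tissue: tumors have low MD and high MK_I
#: (heterogeneous, densely cellular), the peripheral zone has lower MD and
#: higher MK_A than the transitional zone. Absolute values are configuration,
#: not claims about tissue.
DEFAULT_CLASS_RANGES = {
    "tumor": {"md": (0.8, 1.0), "mk_i": (1.0, 1.4), "mk_a": (0.2, 0.4)},
    "PZ": {"md": (1.1, 1.3), "mk_i": (0.5, 0.8), "mk_a": (0.7, 0.9)},
    "TZ": {"md": (1.4, 1.6), "mk_i": (0.2, 0.4), "mk_a": (0.3, 0.5)},
}

CLASS_CODES = {"background": 0, "tumor": 1, "PZ": 2, "TZ": 3}


@dataclass
class PhantomSpec:
    """Configuration of the digital phantom.

    Default grid is 16 x 16 x 4 voxels split into four y-slabs (background,
    tumor-like, PZ-like, TZ-like). ``sigma_rel`` is the Rician noise SD as a
    fraction of S0 (1/30 corresponds to SNR 30 at b = 0).
    """

    shape: tuple = (16, 16, 4)
    class_ranges: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_RANGES.items()})
    labels: np.ndarray | None = None
    s0: float = 100.0
    sigma_rel: float = 1.0 / 30.0
    seed: int = 0
    n_orientations: int = 256
    background_s0_rel: float = 0.01

    def __post_init__(self):
        if np.prod(self.shape) == 0:
            raise ValueError("phantom grid must be nonempty")
        if self.sigma_rel < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.labels is None:
            self.labels = self.default_labels()
        self.labels = np.asarray(self.labels)
        if self.labels.shape != tuple(self.shape):
            raise ValueError("label volume must match the grid shape")
        known = set(CLASS_CODES.values())
        found = set(np.unique(self.labels).tolist())
        if not found <= known:
            raise ValueError(f"unknown class labels: {sorted(found - known)}")

    def default_labels(self) -> np.ndarray:
        labels = np.zeros(self.shape, dtype=np.int16)
        ny = self.shape[1]
        edges = np.linspace(0, ny, 5).astype(int)
        labels[:, edges[1]:edges[2], :] = CLASS_CODES["tumor"]
        labels[:, edges[2]:edges[3], :] = CLASS_CODES["PZ"]
        labels[:, edges[3]:, :] = CLASS_CODES["TZ"]
        return labels


@dataclass
class Phantom:
    """Simulated 4D volume plus per-voxel ground truth."""

    signal: np.ndarray  # (x, y, z, n_volumes)
    labels: np.ndarray  # (x, y, z) int codes per CLASS_CODES
    truth: dict  # parameter name -> (x, y, z) float array (NaN in background)
    affine: np.ndarray
    spec: PhantomSpec

    def write(self, outdir, scheme: EncodingScheme | None = None) -> None:
        """Write NIfTI volumes, a label sidecar JSON and the scheme file."""
        import nibabel as nib

        from .encoding import write_scheme

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(self.signal.astype(np.float64), self.affine), outdir / "signal.nii")
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine), outdir / "labels.nii")
        for name, vol in self.truth.items():
            nib.save(nib.Nifti1Image(vol.astype(np.float64), self.affine), outdir / f"truth_{name}.nii")
        (outdir / "labels.json").write_text(
            json.dumps({v: k for k, v in CLASS_CODES.items()}, indent=2)
        )
        if scheme is not None:
            write_scheme(scheme, outdir / "scheme.txt")


def phantom_rois(labels: np.ndarray, n_per_class: int = 8) -> tuple[np.ndarray, dict]:
    """Split each tissue slab of a phantom into ROIs for group statistics.

    Each class region is divided into ``n_per_class`` contiguous blocks along
    the first axis. Tumor ROIs are assigned Gleason grades cyclically
    (G3+3, G3+4, G4+3), mirroring a cohort with lesions of several grades;
    PZ/TZ blocks keep their zone label. Returns (roi_labels, label_map) ready
    for :func:`dividemri.mapping.extract_roi`.
    """
    labels = np.asarray(labels)
    roi_labels = np.zeros_like(labels, dtype=np.int32)
    label_map: dict[int, str] = {}
    grades = ("G3+3", "G3+4", "G4+3")
    next_id = 1
    for code, cls in [(CLASS_CODES["tumor"], "tumor"), (CLASS_CODES["PZ"], "PZ"), (CLASS_CODES["TZ"], "TZ")]:
        where = np.argwhere(labels == code)
        if where.size == 0:
            continue
        xs = np.unique(where[:, 0])
        chunks = np.array_split(xs, n_per_class)
        for j, chunk in enumerate(chunks):
            if chunk.size == 0:
                continue
            m = (labels == code) & np.isin(np.arange(labels.shape[0])[:, None, None], chunk)
            roi_labels[m] = next_id
            label_map[next_id] = grades[j % 3] if cls == "tumor" else cls
            next_id += 1
    return roi_labels, label_map


def make_phantom(spec: PhantomSpec, scheme: EncodingScheme) -> Phantom:
    """Simulate the phantom: per-voxel DTD draw, forward model, Rician noise.

    Every non-background voxel gets a tensor distribution drawn from its
    class's (MD, MK_I, MK_A) ranges via
    :meth:`TensorDistribution.from_moment_targets`; the exact moments of the
    realized mixture are stored as the ground-truth volumes. Background voxels carry only the
    noise floor (S0 reduced to ``background_s0_rel`` of tissue S0).
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    nvol = len(scheme)
    signal = np.zeros(shape + (nvol,))
    truth = {p: np.full(shape, np.nan) for p in ("md", "mk_i", "mk_a")}
    code_to_class = {v: k for k, v in CLASS_CODES.items()}

    for idx in np.ndindex(shape):
        code = int(spec.labels[idx])
        cls = code_to_class[code]
        if cls == "background":
            signal[idx] = spec.background_s0_rel * spec.s0
            continue
        r = spec.class_ranges[cls]
        md = rng.uniform(*r["md"])
        mk_i = rng.uniform(*r["mk_i"])
        mk_a = rng.uniform(*r["mk_a"])
        dtd = TensorDistribution.from_moment_targets(
            md, mk_i, mk_a, n_orientations=spec.n_orientations, rng=rng
        )
        signal[idx] = simulate_signal(dtd, scheme, s0=spec.s0)
        gt = dtd_moments(dtd)
        truth["md"][idx] = gt.md
        truth["mk_i"][idx] = gt.mk_i
        truth["mk_a"][idx] = gt.mk_a

    sigma = spec.sigma_rel * spec.s0
    noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    signal = add_rician_noise(signal, sigma, rng=noise_rng)
    affine = np.diag([3.0, 3.0, 4.0, 1.0])  # mm voxel size metadata
    return Phantom(signal=signal, labels=spec.labels.copy(), truth=truth, affine=affine, spec=spec)
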