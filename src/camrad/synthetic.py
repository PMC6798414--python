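"""Ground-truth-known synthetic inputs for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* pixel kinetic time-series that are convex mixtures of a small number of
  compartment enhancement curves, with Dirichlet-distributed mixing
  proportions and additive Gaussian noise;
* proportional-hazards survival times linked to a scalar imaging feature;
* block-modular gene expression with one module eigengene planted to
  correlate with an imaging feature at a target Pearson r.

All generators are pure functions of their ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.optimize import brentq

__all__ = [
    "KineticCurveSet",
    "SyntheticTumour",
    "SyntheticCohort",
    "generate_kinetic_curves",
    "generate_mixture_image",
    "generate_survival",
    "generate_expression",
    "generate_cohort",
]

ROLE_ORDER = ("plasma_input", "fast_flow", "slow_flow", "slow_flow_2", "slow_flow_3")


@dataclass
class KineticCurveSet:
    """A set of compartment enhancement curves sampled on a common time grid."""

    timepoints: np.ndarray  # minutes, ascending, length T
    curves: np.ndarray  # J x T, nonnegative
    roles: tuple[str, ...]  # length J

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.curves = np.asarray(self.curves, dtype=float)
        if self.timepoints.size < 3:
            raise ValueError("need at least 3 timepoints")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly ascending")
        if np.any(self.curves < 0):
            raise ValueError("curves must be nonnegative")
        if self.curves.shape != (len(self.roles), self.timepoints.size):
            raise ValueError("curves shape must be (J, T)")


@dataclass
class SyntheticTumour:
    """A 4-D synthetic DCE series with known mixing ground truth."""

    image: np.ndarray  # T x X x Y x Z
    mask: np.ndarray  # X x Y x Z boolean
    true_K: np.ndarray  # N x J proportions for in-mask voxels (C order)
    true_curves: KineticCurveSet
    noise_sigma: float
    seed: int

    @property
    def pixel_matrix(self) -> np.ndarray:
        """N x T matrix of in-mask voxel time-series."""
        return self.image[:, self.mask].T


@dataclass
class SyntheticCohort:
    """Linked imaging-feature / survival / expression data for n subjects."""

    features: pd.DataFrame  # subjects x features
    survival: pd.DataFrame  # columns: time, event
    expression: pd.DataFrame  # genes x subjects
    truth: dict = field(default_factory=dict)


def _gamma_variate(t: np.ndarray, t_peak: float, shape: float, amplitude: float) -> np.ndarray:
    """Normalised gamma-variate: 0 at t=0, peak ``amplitude`` at t=t_peak."""
    tt = np.clip(t, 0.0, None) / t_peak
    with np.errstate(divide="ignore", invalid="ignore"):
        y = amplitude * np.where(tt > 0, tt**shape * np.exp(shape * (1.0 - tt)), 0.0)
    return np.clip(y, 0.0, None)


# Per-role gamma-variate parameters (peak time in minutes, shape, amplitude).
# Plasma input: rapid wash-in, early peak, deep wash-out.  Fast flow: moderate
# peak.  Slow flow: late peak / plateau with the lowest wash-in rate.
_ROLE_PARAMS = {
    "plasma_input": (1.0, 3.0, 1.0),
    "fast_flow": (3.5, 2.0, 1.0),
    "slow_flow": (9.0, 1.3, 0.9),
    "slow_flow_2": (12.0, 1.1, 0.8),
    "slow_flow_3": (15.0, 1.0, 0.7),
}


def generate_kinetic_curves(
    n_compartments: int, timepoints, seed: int = 0, jitter: float = 0.08
) -> KineticCurveSet:
    """Generate ``n_compartments`` nonnegative enhancement curves.

    For three compartments the roles are plasma input (earliest peak,
    fastest wash-out), fast flow, and slow flow (lowest wash-in rate);
    times-to-peak are distinct and ordered plasma < fast <= slow.
    """
    if not 1 <= n_compartments <= 5:
        raise ValueError("n_compartments must be in 1..5")
    t = np.asarray(timepoints, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly ascending")
    rng = np.random.default_rng(seed)
    roles = ROLE_ORDER[:n_compartments]
    curves = np.empty((n_compartments, t.size))
    for j, role in enumerate(roles):
        t_peak, shape, amp = _ROLE_PARAMS[role]
        t_peak = t_peak * (1.0 + jitter * rng.uniform(-1, 1))
        shape = shape * (1.0 + jitter * rng.uniform(-1, 1))
        amp = amp * (1.0 + jitter * rng.uniform(-1, 1))
        curves[j] = _gamma_variate(t, t_peak, shape, amp)
    return KineticCurveSet(timepoints=t, curves=curves, roles=tuple(roles))


def _default_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Centred ellipsoid filling ~80% of each axis."""
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    centre = [(n - 1) / 2.0 for n in shape]
    radii = [max(n * 0.4, 1.0) for n in shape]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii))
    return r2 <= 1.0


def generate_mixture_image(
    curves: KineticCurveSet,
    shape: tuple[int, int, int] = (12, 12, 6),
    dirichlet_alpha=None,
    corner_fraction: float = 0.05,
    noise_sigma: float = 0.0,
    seed: int = 0,
    mask: np.ndarray | None = None,
    smooth_size: int = 3,
) -> SyntheticTumour:
    """Forward-simulate a mixed-voxel DCE series from compartment curves.

    Each in-mask voxel's time-series is ``K @ curves`` for a Dirichlet-drawn
    proportion row ``K``; proportion maps are spatially smoothed (3-voxel
    moving average, then renormalised) so subregions are contiguous, and a
    ``corner_fraction`` of voxels is forced to pure single-compartment
    proportions afterwards so the mixing simplex has occupied corners.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if not 0.0 <= corner_fraction <= 0.5:
        raise ValueError("corner_fraction must be in [0, 0.5]")
    J, T = curves.curves.shape
    mask = _default_mask(tuple(shape)) if mask is None else np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    if n_vox < J:
        raise ValueError(f"mask has {n_vox} voxels, fewer than {J} compartments")
    alpha = np.ones(J) if dirichlet_alpha is None else np.asarray(dirichlet_alpha, dtype=float)
    if alpha.shape != (J,) or np.any(alpha <= 0):
        raise ValueError("dirichlet_alpha must be J positive reals")

    rng = np.random.default_rng(seed)
    K = rng.dirichlet(alpha, size=n_vox)  # N x J

    if smooth_size and smooth_size > 1:
        # smooth each proportion map over the grid, then renormalise in-mask rows
        full = np.zeros(mask.shape + (J,))
        full[mask] = K
        weight = uniform_filter(mask.astype(float), size=smooth_size, mode="constant")
        for j in range(J):
            sm = uniform_filter(full[..., j], size=smooth_size, mode="constant")
            full[..., j] = np.divide(sm, weight, out=np.zeros_like(sm), where=weight > 0)
        K = full[mask]
        K = K / K.sum(axis=1, keepdims=True)

    if corner_fraction > 0:
        # contiguous near-extreme blocks: for compartment j take the voxels
        # most extreme along one spatial axis direction, so pure corners are
        # spatially grouped and survive as contiguous subregion cores
        n_pure = max(1, int(round(corner_fraction * n_vox / J)))
        coords = np.argwhere(mask).astype(float)
        directions = [coords[:, ax] * sgn for ax in range(coords.shape[1]) for sgn in (1, -1)]
        for j in range(J):
            order = np.argsort(-directions[j % len(directions)], kind="stable")
            idx = order[:n_pure]
            K[idx] = 0.0
            K[idx, j] = 1.0

    clean = K @ curves.curves  # N x T
    image = np.zeros((T,) + mask.shape)
    image[:, mask] = clean.T
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    return SyntheticTumour(
        image=image,
        mask=mask,
        true_K=K,
        true_curves=curves,
        noise_sigma=float(noise_sigma),
        seed=int(seed),
    )


def generate_survival(
    feature,
    beta: float = 0.0,
    baseline_scale: float = 5.0,
    censor_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential proportional-hazards event times linked to ``feature``.

    Hazard for subject i is ``exp(beta * feature_i) / baseline_scale``.
    Censoring is independent uniform on (0, c) with c solved numerically so
    the expected censoring fraction equals ``censor_rate``.
    """
    x = np.asarray(feature, dtype=float)
    if x.size == 0:
        raise ValueError("feature vector is empty")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lam = np.exp(beta * x) / baseline_scale
    t_event = rng.exponential(1.0 / lam)

    if censor_rate == 0.0:
        return pd.DataFrame({"time": t_event, "event": np.ones(x.size, dtype=int)})

    def expected_censored(c: float) -> float:
        # P(C < T) = E[exp(-lam C)] for C ~ U(0, c), T ~ Exp(lam)
        z = lam * c
        return float(np.mean((1.0 - np.exp(-z)) / z))

    lo, hi = 1e-6 / lam.mean(), 1e6 / lam.mean()
    c = brentq(lambda v: expected_censored(v) - censor_rate, lo, hi)
    t_cens = rng.uniform(0.0, c, size=x.size)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event})


def generate_expression(
    n_genes: int,
    n_subjects: int,
    module_sizes=(158, 198, 166),
    linked_feature=None,
    target_r: float = 0.59,
    noise_sd: float = 0.3,
    loading: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Block-modular expression with one module eigengene linked to a feature.

    Each module's genes are ``loading * latent + noise``; the first module's
    latent is constructed to correlate with ``linked_feature`` at ``target_r``
    in expectation.  Remaining genes are independent noise.  Returns the
    genes x subjects matrix and a truth dict (module labels, linked module,
    target r, seed).
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    module_sizes = tuple(int(s) for s in module_sizes)
    if sum(module_sizes) > n_genes:
        raise ValueError("sum of module_sizes exceeds n_genes")
    if not abs(target_r) < 1:
        raise ValueError("|target_r| must be < 1")
    rng = np.random.default_rng(seed)

    def z(v):
        v = np.asarray(v, dtype=float)
        return (v - v.mean()) / v.std()

    latents = []
    for k in range(len(module_sizes)):
        raw = rng.normal(size=n_subjects)
        if k == 0 and linked_feature is not None:
            f = z(linked_feature)
            resid = raw - f * (raw @ f) / n_subjects
            while resid.std() < 1e-8:  # raw (numerically) collinear with the feature
                raw = rng.normal(size=n_subjects)
                resid = raw - f * (raw @ f) / n_subjects
            raw = target_r * f + np.sqrt(1.0 - target_r**2) * z(resid)
        latents.append(z(raw))

    values = rng.normal(0.0, 1.0, size=(n_genes, n_subjects))
    labels = np.full(n_genes, "noise", dtype=object)
    g = 0
    for k, size in enumerate(module_sizes):
        load = loading * rng.uniform(0.8, 1.2, size=size)
        sign = rng.choice([1.0, -1.0], size=size, p=[0.9, 0.1])
        block = (sign * load)[:, None] * latents[k][None, :]
        block = block + rng.normal(0.0, noise_sd * loading, size=block.shape)
        values[g : g + size] = block
        labels[g : g + size] = f"module_{k + 1}"
        g += size

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    subject_ids = [f"s{i:04d}" for i in range(n_subjects)]
    expr = pd.DataFrame(values, index=gene_ids, columns=subject_ids)
    truth = {
        "module_labels": pd.Series(labels, index=gene_ids),
        "latents": np.array(latents),
        "linked_module": "module_1",
        "target_r": float(target_r),
        "seed": int(seed),
    }
    return expr, truth


def generate_cohort(
    n_subjects: int = 87,
    n_genes: int = 1200,
    module_sizes=(158, 198, 166),
    target_r: float = 0.59,
    survival_beta: float = 0.7,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> SyntheticCohort:
    """A linked cohort: one imaging feature, PH survival, modular expression."""
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed).generate_state(3)
    feature = rng.normal(size=n_subjects)
    survival = generate_survival(
        feature, beta=survival_beta, censor_rate=censor_rate, seed=int(ss[1] % 2**31)
    )
    expr, truth = generate_expression(
        n_genes,
        n_subjects,
        module_sizes=module_sizes,
        linked_feature=feature,
        target_r=target_r,
        seed=int(ss[2] % 2**31),
    )
    features = pd.DataFrame({"max_probability_fast": feature}, index=expr.columns)
    survival.index = expr.columns
    truth.update({"survival_beta": float(survival_beta), "censor_rate": float(censor_rate)})
    return SyntheticCohort(features=features, survival=survival, expression=expr, truth=truth)
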