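"""Synthetic knee phantom generator with analytic ground truth.

Emulates what the real pipeline gets from segmented qMRI: integer label
volumes for bones, cartilage and menisci; multi-echo signal stacks obeying
the mono-exponential relaxometry model; population shape variation from a
known low-rank deformation model; and cohort tables with planted
confounding and logistic outcomes.

Geometry is deliberately parametric-primitive (ellipsoidal bones, offset
cartilage shells of known thickness, torus-sector menisci) so every
downstream measurement has a closed-form truth.  Population variation is a
low-rank field: subject landmarks are ``mean + B @ scores`` with ``B``
orthonormal over the landmark vector, i.e. mode scores use the same
landmark-space norm convention as statistical-shape-model scores, which
makes per-mode variance recovery well-posed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import EchoSeries, GridSpec, LabelVolume

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "KneePhantom",
    "make_knee_labelmap",
    "make_echo_series",
    "make_population",
    "sample_landmark_population",
    "make_cohort_table",
    "slab_labelmap",
    "spherical_shell_labelmap",
]

ALL_TISSUES = (
    "femur",
    "tibia",
    "patella",
    "femoral_cartilage",
    "tibial_cartilage",
    "patellar_cartilage",
    "medial_meniscus",
    "lateral_meniscus",
)
LABELS = {name: i + 1 for i, name in enumerate(ALL_TISSUES)}

# (center mm, semi-axes mm); the grid is centered on the world origin
_BONES = {
    "femur": ((0.0, 0.0, 24.0), (20.0, 17.0, 18.0)),
    "tibia": ((0.0, 0.0, -21.0), (19.0, 16.0, 15.0)),
    "patella": ((30.0, 0.0, 10.0), (7.0, 9.0, 9.0)),
}
# cartilage: (parent bone, cap axis, cap sign, cap cosine threshold)
_CARTILAGE = {
    "femoral_cartilage": ("femur", 2, -1, 0.35),
    "tibial_cartilage": ("tibia", 2, +1, 0.35),
    "patellar_cartilage": ("patella", 0, -1, 0.45),
}
# menisci: (z center, major radius, tube radius, azimuth range rad)
_MENISCI = {
    "medial_meniscus": (-2.0, 17.0, 2.5, (np.deg2rad(25), np.deg2rad(155))),
    "lateral_meniscus": (-2.0, 17.0, 2.5, (np.deg2rad(205), np.deg2rad(335))),
}
SHAPE_TISSUES = ("femur", "tibia", "patella", "medial_meniscus", "lateral_meniscus")

_DEFORMATION_PERIOD_MM = 90.0  # spatial wavelength of the basis fields


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the synthetic population.

    ``deformation_sds`` are per-mode score standard deviations in the
    orthonormal landmark-basis convention (a score of s displaces the
    landmark vector by s mm in 3L-norm, i.e. RMS per-landmark displacement
    s / sqrt(3 L)).  Defaults give sub-millimetre RMS surface variation,
    small against the inter-tissue gaps so tissue labels stay disjoint.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    tissues: tuple[str, ...] = ALL_TISSUES
    n_subjects: int = 20
    n_deformation_modes: int = 3
    deformation_sds: tuple[float, ...] = (20.0, 14.0, 8.0)
    noise_sd: float = 2.0
    echo_times: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0)
    seed: int = 0
    n_landmarks: int = 500
    cartilage_thickness_mm: float = 2.5
    thickness_variation: float = 0.10  # fractional azimuthal modulation
    rician_noise: bool = False

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 positive integers")
        if any(s <= 0 for s in self.spacing) or len(self.spacing) != 3:
            raise ValueError("spacing must be 3 positive reals")
        unknown = set(self.tissues) - set(ALL_TISSUES)
        if unknown:
            raise ValueError(f"unknown tissues: {sorted(unknown)}")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.n_deformation_modes < 0:
            raise ValueError("n_deformation_modes must be non-negative")
        if len(self.deformation_sds) != self.n_deformation_modes:
            raise ValueError(
                f"deformation_sds has length {len(self.deformation_sds)}, "
                f"expected n_deformation_modes={self.n_deformation_modes}"
            )
        if any(s <= 0 for s in self.deformation_sds):
            raise ValueError("deformation_sds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 3 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError(
                "echo_times must be >= 3 strictly increasing positive values"
            )

    @property
    def grid(self) -> GridSpec:
        origin = tuple(
            -(n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.spacing)
        )
        return GridSpec(self.grid_shape, self.spacing, origin)


# per-tissue mono-exponential signal parameters: alpha, T2 deep, T2 superficial,
# offset C (signal units / ms).  Deep vs superficial only differs for cartilage.
DEFAULT_SIGNAL_PARAMS = {
    "femur": (25.0, 15.0, 15.0, 1.0),
    "tibia": (25.0, 15.0, 15.0, 1.0),
    "patella": (25.0, 15.0, 15.0, 1.0),
    "femoral_cartilage": (100.0, 35.0, 55.0, 2.0),
    "tibial_cartilage": (100.0, 35.0, 55.0, 2.0),
    "patellar_cartilage": (100.0, 35.0, 55.0, 2.0),
    "medial_meniscus": (60.0, 18.0, 18.0, 1.0),
    "lateral_meniscus": (60.0, 18.0, 18.0, 1.0),
}


@dataclass
class GroundTruth:
    """Everything needed to reconstruct the observables for one subject."""

    config: PhantomConfig
    scores: np.ndarray  # (n_modes,) this subject's deformation scores
    ref_landmarks: dict[str, np.ndarray]  # tissue -> (L, 3) mm
    basis: dict[str, np.ndarray]  # tissue -> (3L, n_modes), orthonormal columns
    thickness: dict[str, tuple[float, float]]  # cartilage -> (t0 mm, variation)
    signal_params: dict[str, tuple[float, float, float, float]]
    subject_seed: int
    outcome_beta: np.ndarray | None = None
    confounder_shift: dict[str, float] | None = None

    def landmarks(self, tissue: str) -> np.ndarray:
        """True deformed landmark coordinates (L, 3) for a shape tissue."""
        ref = self.ref_landmarks[tissue]
        if self.scores.size == 0:
            return ref.copy()
        disp = (self.basis[tissue] @ self.scores).reshape(ref.shape)
        return ref + disp

    def thickness_at(self, cart_tissue: str, directions: np.ndarray) -> np.ndarray:
        """Analytic shell thickness (mm) for unit radial directions (N, 3)."""
        t0, var = self.thickness[cart_tissue]
        az = np.arctan2(directions[:, 1], directions[:, 0])
        return t0 * (1.0 + var * np.sin(az))


class KneePhantom:
    """Parametric knee geometry + deformation model for one configuration."""

    def __init__(self, config: PhantomConfig):
        self.config = config
        self.grid = config.grid
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
        K = config.n_deformation_modes
        self.ref_landmarks: dict[str, np.ndarray] = {
            tissue: self._reference_surface(tissue, config.n_landmarks)
            for tissue in SHAPE_TISSUES
            if tissue in config.tissues
        }
        # raw smooth fields f_j(x) = v_j sin(2 pi k_j.x / P + phi_j),
        # orthonormalized at each tissue's reference landmarks.  Redraw the
        # wave directions until the orthonormalizing mix is well conditioned
        # for every tissue: a near-degenerate raw set would make the
        # continuous field between landmarks much larger than its
        # at-landmark norm and risk tissues interpenetrating.
        coeff_cap = 5.0 / max(np.sqrt(3.0 * config.n_landmarks), 1.0)
        for _attempt in range(200):
            self._field_dirs = _random_unit(rng, K)
            self._wave_dirs = _random_unit(rng, K)
            self._phases = rng.uniform(0, 2 * np.pi, size=K)
            self.basis = {}
            self._coeffs = {}  # raw-field -> orthonormal mixing
            ok = True
            for tissue, ref in self.ref_landmarks.items():
                if K == 0:
                    self.basis[tissue] = np.zeros((ref.size, 0))
                    self._coeffs[tissue] = np.zeros((0, 0))
                    continue
                raw = np.stack(
                    [self._raw_field(j, ref).ravel() for j in range(K)], axis=1
                )  # (3L, K)
                q, r = np.linalg.qr(raw)
                sign = np.sign(np.diag(r))
                sign[sign == 0] = 1.0
                q, r = q * sign, r * sign[:, None]
                coeffs = np.linalg.inv(r)  # raw @ inv(r) == q
                if np.abs(coeffs).max() > coeff_cap:
                    ok = False
                    break
                self.basis[tissue] = q
                self._coeffs[tissue] = coeffs
            if ok:
                break
        else:
            raise GeometryError(
                "could not draw a well-conditioned deformation basis"
            )

        self.thickness = {
            c: (config.cartilage_thickness_mm, config.thickness_variation)
            for c in _CARTILAGE
            if c in config.tissues
        }

    # ----- geometry ---------------------------------------------------------

    def _reference_surface(self, tissue: str, n: int) -> np.ndarray:
        if tissue in _BONES:
            center, radii = _BONES[tissue]
            dirs = _fibonacci_sphere(n)
            return np.asarray(center) + dirs * np.asarray(radii)
        z0, R, r, (a0, a1) = _MENISCI[tissue]
        # parameter grid over (azimuth, tube angle)
        m = int(np.ceil(np.sqrt(n)))
        theta = np.linspace(a0, a1, m)
        phi = np.linspace(0, 2 * np.pi, m, endpoint=False)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        tt, pp = tt.ravel()[:n], pp.ravel()[:n]
        if tt.size < n:  # pad by repeating with jittered tube angle
            reps = n - tt.size
            tt = np.concatenate([tt, tt[:reps]])
            pp = np.concatenate([pp, pp[:reps] + np.pi / m])
        x = (R + r * np.cos(pp)) * np.cos(tt)
        y = (R + r * np.cos(pp)) * np.sin(tt)
        z = z0 + r * np.sin(pp)
        return np.column_stack([x, y, z])

    def _raw_field(self, j: int, points: np.ndarray) -> np.ndarray:
        arg = (
            2 * np.pi * (points @ self._wave_dirs[j]) / _DEFORMATION_PERIOD_MM
            + self._phases[j]
        )
        return np.sin(arg)[:, None] * self._field_dirs[j]

    def _displacement(self, tissue: str, points: np.ndarray, scores) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if scores.size == 0:
            return np.zeros_like(points)
        w = self._coeffs[tissue] @ scores  # raw-field weights
        disp = np.zeros_like(points)
        for j in range(w.size):
            disp += w[j] * self._raw_field(j, points)
        return disp

    def labelmap(self, subject_scores) -> LabelVolume:
        """Integer label volume for one subject's deformation scores."""
        cfg = self.config
        scores = np.asarray(subject_scores, dtype=float)
        if scores.shape != (cfg.n_deformation_modes,):
            raise ValueError(
                f"expected {cfg.n_deformation_modes} scores, got {scores.shape}"
            )
        grid = self.grid
        ax = grid.world_coords()
        X = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
        spacing = np.asarray(cfg.spacing)
        shape = cfg.grid_shape
        masks: dict[str, np.ndarray] = {}
        for bone, (center, radii) in _BONES.items():
            if bone not in cfg.tissues:
                continue
            xw = X - self._displacement(bone, X, scores)
            u = (xw - np.asarray(center)) / np.asarray(radii)
            masks[bone] = (np.einsum("ij,ij->i", u, u) <= 1.0).reshape(shape)
        for cart, (bone, axis, sign, cos_thr) in _CARTILAGE.items():
            if cart not in cfg.tissues:
                continue
            if bone not in masks:
                raise GeometryError(f"{cart} requires its parent bone {bone}")
            dist = ndimage.distance_transform_edt(~masks[bone], sampling=spacing)
            center = np.asarray(_BONES[bone][0])
            t0, var = self.thickness[cart]
            w = X - center
            w /= np.maximum(np.linalg.norm(w, axis=1, keepdims=True), 1e-12)
            az = np.arctan2(w[:, 1], w[:, 0])
            t_field = (t0 * (1.0 + var * np.sin(az))).reshape(shape)
            cap = (sign * w[:, axis] > cos_thr).reshape(shape)
            masks[cart] = (dist > 0) & (dist <= t_field) & cap
        for men, (z0, R, r, (a0, a1)) in _MENISCI.items():
            if men not in cfg.tissues:
                continue
            xw = X - self._displacement(men, X, scores)
            rad = np.hypot(xw[:, 0], xw[:, 1])
            az = np.mod(np.arctan2(xw[:, 1], xw[:, 0]), 2 * np.pi)
            tube = (rad - R) ** 2 + (xw[:, 2] - z0) ** 2
            masks[men] = ((tube <= r**2) & (az >= a0) & (az <= a1)).reshape(shape)

        data = np.zeros(shape, dtype=np.int32)
        occupied = np.zeros(shape, dtype=bool)
        for tissue in ALL_TISSUES:
            if tissue not in masks:
                continue
            m = masks[tissue]
            if not m.any():
                raise GeometryError(f"tissue {tissue} produced an empty mask")
            if _touches_boundary(m):
                raise GeometryError(f"tissue {tissue} exceeds the grid")
            clash = m & occupied
            if clash.any():
                # thin contact overlaps at extreme deformations are carved in
                # canonical order (tissues cannot interpenetrate); losing a
                # substantial fraction of a tissue means broken geometry
                if clash.sum() > 0.10 * m.sum():
                    raise GeometryError(
                        f"tissue {tissue} overlaps a previously placed label "
                        f"({int(clash.sum())} of {int(m.sum())} voxels)"
                    )
                m = m & ~occupied
            data[m] = LABELS[tissue]
            occupied |= m
        return LabelVolume(data=data, grid=grid, labels=dict(LABELS))

    def subject_truth(self, scores, subject_seed: int | None = None) -> GroundTruth:
        return GroundTruth(
            config=self.config,
            scores=np.asarray(scores, dtype=float),
            ref_landmarks=self.ref_landmarks,
            basis=self.basis,
            thickness=self.thickness,
            signal_params=dict(DEFAULT_SIGNAL_PARAMS),
            subject_seed=self.config.seed if subject_seed is None else subject_seed,
        )


def make_knee_labelmap(config: PhantomConfig, subject_scores) -> LabelVolume:
    """One subject's label volume; mean geometry at all-zero scores."""
    return KneePhantom(config).labelmap(subject_scores)


def parameter_volumes(
    labelmap: LabelVolume, truth: GroundTruth
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel true (alpha, T2, C) volumes implied by the label map.

    Cartilage is split into a deep and a superficial layer at half the base
    shell thickness (depth measured from the parent bone surface); all other
    tissues are uniform.  Background carries zero signal.
    """
    shape = labelmap.data.shape
    spacing = labelmap.grid.spacing
    alpha = np.zeros(shape)
    t2 = np.full(shape, np.inf)
    c = np.zeros(shape)
    for tissue, (a, t2_deep, t2_sup, off) in truth.signal_params.items():
        if tissue not in labelmap.labels:
            continue
        m = labelmap.mask(tissue)
        if not m.any():
            continue
        alpha[m], c[m] = a, off
        if tissue in _CARTILAGE and t2_deep != t2_sup:
            bone = _CARTILAGE[tissue][0]
            dist = ndimage.distance_transform_edt(
                ~labelmap.mask(bone), sampling=spacing
            )
            t0 = truth.thickness[tissue][0]
            deep = m & (dist <= t0 / 2.0)
            t2[deep] = t2_deep
            t2[m & ~deep] = t2_sup
        else:
            t2[m] = t2_deep
    return alpha, t2, c


def make_echo_series(
    labelmap: LabelVolume, truth: GroundTruth, config: PhantomConfig
) -> EchoSeries:
    """Multi-echo stack: S(TE) = alpha * exp(-TE / T2) + C plus noise.

    Noiseless when ``config.noise_sd == 0``; Gaussian by default, Rician
    (magnitude of complex Gaussian) behind ``config.rician_noise``.
    """
    alpha, t2, c = parameter_volumes(labelmap, truth)
    te = np.asarray(config.echo_times, dtype=float)
    with np.errstate(divide="ignore"):
        decay = np.exp(-te[:, None, None, None] / t2[None])
    signals = alpha[None] * decay + c[None]
    if config.noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([truth.subject_seed, 104729])
        )
        if config.rician_noise:
            n1 = rng.normal(0, config.noise_sd, signals.shape)
            n2 = rng.normal(0, config.noise_sd, signals.shape)
            signals = np.hypot(signals + n1, n2)
        else:
            signals = signals + rng.normal(0, config.noise_sd, signals.shape)
    return EchoSeries(signals=signals, echo_times=te, grid=labelmap.grid)


def draw_scores(config: PhantomConfig) -> np.ndarray:
    """Per-subject deformation scores, score_j ~ Normal(0, deformation_sds_j^2)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 15485863]))
    sds = np.asarray(config.deformation_sds, dtype=float)
    return rng.normal(0.0, 1.0, size=(config.n_subjects, sds.size)) * sds


def make_population(
    config: PhantomConfig, volumes: bool = True
) -> list[tuple[LabelVolume | None, EchoSeries | None, GroundTruth]]:
    """Draw a synthetic population; ``volumes=False`` keeps ground truth only."""
    if config.n_subjects < config.n_deformation_modes + 2:
        raise ValueError(
            "n_subjects must be at least n_deformation_modes + 2 for a "
            "population shape model to be identifiable"
        )
    phantom = KneePhantom(config)
    scores = draw_scores(config)
    out = []
    for i in range(config.n_subjects):
        truth = phantom.subject_truth(scores[i], subject_seed=config.seed * 100003 + i)
        lab = echo = None
        if volumes:
            lab = phantom.labelmap(scores[i])
            echo = make_echo_series(lab, truth, config)
        out.append((lab, echo, truth))
    return out


def sample_landmark_population(
    config: PhantomConfig,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Fast path: true landmark matrices per shape tissue, no voxelization.

    Returns (scores (n, K), {tissue: (n, 3L) matrix}).  This is the analytic
    low-rank population the voxel pipeline is supposed to recover.
    """
    phantom = KneePhantom(config)
    scores = draw_scores(config)
    mats = {}
    for tissue, ref in phantom.ref_landmarks.items():
        base = ref.ravel()[None, :]
        mats[tissue] = base + scores @ phantom.basis[tissue].T
    return scores, mats


# ----- cohort tables --------------------------------------------------------

CONTINUOUS_COVARIATES = {"age": (61.0, 9.2), "bmi": (28.6, 4.8), "pain": (82.0, 16.0)}
CATEGORICAL_COVARIATES = {
    "sex": (0.58, 0.42),
    "race": (0.78, 0.18, 0.04),
    "injury_history": (0.75, 0.25),
}
N_VISITS = 5


def make_cohort_table(
    config: PhantomConfig,
    feature_scores: pd.DataFrame,
    outcome: str = "oa_incidence",
    beta0: float = -1.0,
    beta: dict[str, float] | None = None,
    gamma: dict[str, float] | None = None,
    confounder_shift: dict[str, float] | None = None,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Covariate/outcome table with planted confounding and known coefficients.

    The binary outcome is drawn from ``logit(p) = beta0 + sum beta_j f_j +
    sum gamma_c z(cov_c)``; afterwards the configured covariates are shifted
    by ``confounder_shift[c]`` standard deviations in the case group, so the
    pre-matching standardized mean difference is the planted shift (plus any
    gamma-induced association).  Longitudinal KLG grades and surgery flags
    are emitted so that outcome derivation reproduces the drawn labels.
    """
    if feature_scores.shape[0] != config.n_subjects:
        raise ValueError(
            f"feature_scores has {feature_scores.shape[0]} rows, "
            f"expected n_subjects={config.n_subjects}"
        )
    if missing_rate >= 1.0:
        raise ValueError("requested missingness covers an entire column")
    if outcome not in ("oa_incidence", "knee_replacement"):
        raise ValueError(f"unknown outcome {outcome!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 32452843])
    )
    n = config.n_subjects
    beta = beta or {}
    gamma = gamma or {}
    confounder_shift = confounder_shift or {}

    cov = pd.DataFrame(index=feature_scores.index)
    for name, (mu, sd) in CONTINUOUS_COVARIATES.items():
        cov[name] = rng.normal(mu, sd, n)
    cov["pain"] = cov["pain"].clip(0, 100)
    for name, probs in CATEGORICAL_COVARIATES.items():
        cov[name] = rng.choice(len(probs), size=n, p=probs)

    logit = np.full(n, beta0, dtype=float)
    for col, b in beta.items():
        logit += b * feature_scores[col].to_numpy(dtype=float)
    for col, g in gamma.items():
        v = cov[col].to_numpy(dtype=float)
        logit += g * (v - v.mean()) / max(v.std(), 1e-12)
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    for col, shift in confounder_shift.items():
        sd = CONTINUOUS_COVARIATES[col][1] if col in CONTINUOUS_COVARIATES else cov[col].std()
        cov.loc[y == 1, col] = cov.loc[y == 1, col] + shift * sd

    table = feature_scores.copy()
    table = pd.concat([table, cov], axis=1)
    table["side"] = "right"
    table["outcome"] = y

    # longitudinal KLG + surgery flags consistent with the outcome definition
    klg = np.zeros((n, N_VISITS), dtype=int)
    surgery = np.zeros(n, dtype=int)
    baseline = rng.integers(0, 2, size=n)  # KLG < 2 at baseline for everyone
    klg[:] = baseline[:, None]
    if outcome == "oa_incidence":
        onset = rng.integers(1, N_VISITS, size=n)
        for i in np.nonzero(y == 1)[0]:
            klg[i, onset[i]:] = rng.integers(2, 5)
    else:
        # KR cases may or may not have radiographic OA; surgery defines them
        surgery[y == 1] = 1
        prog = rng.uniform(size=n) < 0.5
        onset = rng.integers(1, N_VISITS, size=n)
        for i in np.nonzero((y == 1) & prog)[0]:
            klg[i, onset[i]:] = rng.integers(2, 5)
    for v in range(N_VISITS):
        table[f"klg_v{v}"] = klg[:, v]
    table["surgery"] = surgery

    if missing_rate > 0:
        for col in list(CONTINUOUS_COVARIATES) + list(CATEGORICAL_COVARIATES):
            holes = rng.uniform(size=n) < missing_rate
            if holes.all():
                raise ValueError(f"requested missingness removed all of {col!r}")
            table.loc[holes, col] = np.nan

    truth = GroundTruth(
        config=config,
        scores=np.zeros(0),
        ref_landmarks={},
        basis={},
        thickness={},
        signal_params={},
        subject_seed=config.seed if seed is None else seed,
        outcome_beta=np.array([beta.get(c, 0.0) for c in feature_scores.columns]),
        confounder_shift=dict(confounder_shift),
    )
    return table, truth


# ----- analytic test shapes -------------------------------------------------


def slab_labelmap(
    thickness_voxels: int = 5,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    shape: tuple[int, int, int] = (40, 40, 24),
    axis: int = 2,
    label: int = 1,
) -> LabelVolume:
    """Axis-aligned slab of known thickness — the simplest thickness oracle."""
    data = np.zeros(shape, dtype=np.int32)
    lo = (shape[axis] - thickness_voxels) // 2
    sl = [slice(None)] * 3
    sl[axis] = slice(lo, lo + thickness_voxels)
    data[tuple(sl)] = label
    grid = GridSpec(shape, spacing)
    return LabelVolume(data=data, grid=grid, labels={"slab": label})


def spherical_shell_labelmap(
    outer_mm: float = 20.0,
    inner_mm: float = 15.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    margin_mm: float = 4.0,
    label: int = 1,
) -> LabelVolume:
    """Spherical shell of analytic thickness ``outer_mm - inner_mm``."""
    if inner_mm >= outer_mm:
        raise ValueError("inner radius must be smaller than outer radius")
    shape = tuple(
        int(np.ceil(2 * (outer_mm + margin_mm) / s)) | 1 for s in spacing
    )
    grid = GridSpec(shape, spacing, tuple(-(n - 1) * s / 2 for n, s in zip(shape, spacing)))
    ax = grid.world_coords()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    data = ((r >= inner_mm) & (r <= outer_mm)).astype(np.int32) * label
    return LabelVolume(data=data, grid=grid, labels={"shell": label})


def save_ground_truth(truth: GroundTruth, path) -> None:
    """JSON sidecar with the scalar ground truth (arrays summarized)."""
    payload = {
        "scores": truth.scores.tolist(),
        "thickness": truth.thickness,
        "signal_params": truth.signal_params,
        "subject_seed": truth.subject_seed,
        "outcome_beta": None
        if truth.outcome_beta is None
        else truth.outcome_beta.tolist(),
        "confounder_shift": truth.confounder_shift,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _random_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-12)


def _touches_boundary(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
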