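"""Pharmacophore conditioning of a pretrained reverse-diffusion sampler.

The engine wraps any denoiser conforming to :class:`DenoiserInterface` and,
inside the reverse loop, applies three modifications without touching the
model itself:

* **position anchoring** — masked atom slots are pulled toward their bound
  pharmacophore points with a schedule weight ``gamma_t`` that grows as the
  reverse process approaches t = 1, ending in a hard-anchor window where
  ``gamma = 1`` ("firmly anchor in place");
* **clash guidance** — the sampling mean is shifted by
  ``-lambda * Sigma_t * grad L(R_t)`` where ``L`` penalizes atoms closer to a
  smoothed (soft-min) protein surface than a clash threshold;
* **atom-type clamping** — user-fixed elements overwrite masked slots every
  step; bond states are taken from the denoiser unchanged.

Each requested ligand is given up to ``max_attempts`` full trajectories and
is accepted on the first pose that satisfies the pharmacophore spec.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from scipy.special import logsumexp, softmax

from .errors import ConfigError, StepError
from .molio import Molecule3D, ProteinContext
from .pharmacophore import ConstraintSpec, satisfaction


# ---------------------------------------------------------------------------
# Schedule

def default_gamma(T: int, hard_anchor_fraction: float = 0.1) -> np.ndarray:
    """Anchoring weights gamma_t for t = 1..T (index 0 is t = 1).

    gamma_t = min(1, (1 - t/T)^2 / (1 - f)), clipped to exactly 1 inside the
    final ceil(f*T) steps of the reverse process (small t).
    """
    f = hard_anchor_fraction
    t = np.arange(1, T + 1, dtype=float)
    g = np.minimum(1.0, (1.0 - t / T) ** 2 / max(1.0 - f, 1e-12))
    n_hard = math.ceil(f * T)
    if n_hard > 0:
        g[:n_hard] = 1.0
    return g


@dataclass
class ScheduleSpec:
    """Diffusion schedule: step count T, noise scales beta_t, step variances
    Sigma_t (default beta_t), anchoring weights gamma_t.

    Vectors are indexed by ``t - 1`` for t in 1..T.  ``gamma`` must be
    monotone non-increasing in t and exactly 1 inside the hard-anchor window
    (the final ``ceil(hard_anchor_fraction * T)`` reverse steps).
    """

    T: int
    beta: np.ndarray
    sigma_sq: np.ndarray | None = None
    gamma: np.ndarray | None = None
    hard_anchor_fraction: float = 0.1

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.T,):
            raise ValueError("beta must have length T")
        if np.any(self.beta < 0) or np.any(self.beta > 1):
            raise ValueError("beta entries must lie in [0, 1]")
        if self.sigma_sq is None:
            self.sigma_sq = self.beta.copy()
        self.sigma_sq = np.asarray(self.sigma_sq, dtype=float)
        if self.sigma_sq.shape != (self.T,):
            raise ValueError("sigma_sq must have length T")
        if self.gamma is None:
            self.gamma = default_gamma(self.T, self.hard_anchor_fraction)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.shape != (self.T,):
            raise ValueError("gamma must have length T")
        if np.any(np.diff(self.gamma) > 1e-12):
            raise ValueError("gamma must be monotone non-increasing in t")
        n_hard = math.ceil(self.hard_anchor_fraction * self.T)
        if n_hard and not np.all(self.gamma[:n_hard] == 1.0):
            raise ValueError("gamma must equal 1 inside the hard-anchor window")
        # alpha_bar_t = prod_{s<=t} (1 - beta_s); index 0 corresponds to t=1.
        self.alpha_bar = np.cumprod(1.0 - self.beta)

    def _check_t(self, t: int) -> None:
        if not 1 <= t <= self.T:
            raise StepError(f"step t={t} outside [1, {self.T}]")

    def beta_t(self, t: int) -> float:
        self._check_t(t)
        return float(self.beta[t - 1])

    def sigma_sq_t(self, t: int) -> float:
        self._check_t(t)
        return float(self.sigma_sq[t - 1])

    def gamma_t(self, t: int) -> float:
        self._check_t(t)
        return float(self.gamma[t - 1])

    def alpha_bar_t(self, t: int) -> float:
        if t == 0:
            return 1.0
        self._check_t(t)
        return float(self.alpha_bar[t - 1])


# ---------------------------------------------------------------------------
# Denoiser contract

@dataclass
class DenoiserOutput:
    """One reverse step's predictions: position means mu (N x 3), atom-type
    logits (N x K), bond logits (N x N x B), and the step variance."""

    mu: np.ndarray
    type_logits: np.ndarray
    bond_logits: np.ndarray
    sigma_sq_t: float

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        n = self.mu.shape[0]
        if self.mu.shape != (n, 3):
            raise ValueError("mu must be N x 3")
        if self.type_logits.shape[0] != n or self.bond_logits.shape[:2] != (n, n):
            raise ValueError("logit shapes inconsistent with N")
        if not (np.all(np.isfinite(self.mu))
                and np.all(np.isfinite(self.type_logits))
                and np.all(np.isfinite(self.bond_logits))):
            raise ValueError("denoiser output must be finite")


@runtime_checkable
class DenoiserInterface(Protocol):
    """Contract any pluggable denoiser must fulfill."""

    def denoise(self, positions: np.ndarray, types: np.ndarray,
                bonds: np.ndarray, t: int) -> DenoiserOutput: ...

    def vocabulary(self) -> tuple[str, ...]: ...

    def schedule(self) -> ScheduleSpec: ...


class MolDiffAdapter:
    """Stub adapter documenting the contract for a trained bond-diffusion model.

    A real adapter must load the pretrained checkpoint, expose its atom-type
    vocabulary and noise schedule through :meth:`vocabulary` and
    :meth:`schedule`, and map ``denoise`` onto one reverse step of the network
    (positions in Angstrom, mean-centered the way the model was trained).
    Checkpoint loading is deliberately not implemented here.
    """

    def __init__(self, checkpoint_path: str):
        self.checkpoint_path = checkpoint_path

    def denoise(self, positions, types, bonds, t):  # pragma: no cover - stub
        raise NotImplementedError(
            "MolDiffAdapter is a documentation stub; supply a trained model "
            "through your own DenoiserInterface implementation")

    vocabulary = denoise
    schedule = denoise


# ---------------------------------------------------------------------------
# Configuration / report

INIT_MODES = ("around_points", "pure_random", "noised_reference")


@dataclass
class GuidanceConfig:
    """Knobs of the conditioning engine.

    ``lam`` is the clash-guidance strength (0 disables guidance);
    ``init_mode`` selects among the three initialization/reference ablation
    variants; ``init_spread`` is the s.d. (Angstrom) of the initial position
    noise; ``grad_at`` chooses where the clash gradient is evaluated.
    """

    lam: float = 0.1
    max_attempts: int = 3
    init_mode: str = "around_points"
    init_spread: float = 1.0
    seed: int = 0
    grad_at: str = "sample"  # "sample" (R_t) or "mean" (mu_theta)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ConfigError("guidance strength lambda must be >= 0")
        if self.max_attempts < 1:
            raise ConfigError("max_attempts must be >= 1")
        if self.init_mode not in INIT_MODES:
            raise ConfigError(f"init_mode must be one of {INIT_MODES}")
        if not self.init_spread > 0:
            raise ConfigError("init_spread must be > 0")
        if self.grad_at not in ("sample", "mean"):
            raise ConfigError("grad_at must be 'sample' or 'mean'")


@dataclass
class AttemptRecord:
    accepted: bool
    satisfaction_report: list[dict]
    clash_loss_final: float
    clash_loss_max: float


@dataclass
class GenerationReport:
    """Outcome of a sampling run: accepted poses plus per-ligand bookkeeping."""

    requested: int
    accepted: list[Molecule3D] = field(default_factory=list)
    attempts_used: list[int] = field(default_factory=list)
    attempt_log: list[list[AttemptRecord]] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    @property
    def acceptance_fraction(self) -> float:
        return self.n_accepted / self.requested if self.requested else float("nan")


# ---------------------------------------------------------------------------
# Elementary operations

def init_positions(
    spec: ConstraintSpec,
    n_atoms: int,
    mode: str = "around_points",
    spread: float = 1.0,
    seed: int | np.random.Generator = 0,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Draw initial atom positions for the reverse process.

    ``around_points``: masked slot k is drawn isotropic-Gaussian around its
    bound point; free slots around the centroid of all points.
    ``pure_random``: every slot isotropic-Gaussian around ``center`` (the
    pocket origin; default the point centroid, else the origin).
    """
    if n_atoms < int(spec.mask.sum()):
        raise ValueError("n_atoms smaller than number of masked slots")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "noised_reference":
        mode = "around_points"  # the ablation differs in reference handling, not init
    if mode == "around_points" and spec.n_points == 0:
        warnings.warn("empty constraint spec: falling back to pure_random init",
                      stacklevel=2)
        mode = "pure_random"
    centers = _init_centers(spec, n_atoms, mode, center)
    return centers + spread * rng.standard_normal((n_atoms, 3))


def _init_centers(spec: ConstraintSpec, n_atoms: int, mode: str,
                  center: np.ndarray | None) -> np.ndarray:
    if mode == "pure_random" or spec.n_points == 0:
        if center is None:
            center = (spec.point_positions().mean(axis=0)
                      if spec.n_points else np.zeros(3))
        return np.broadcast_to(np.asarray(center, dtype=float), (n_atoms, 3)).copy()
    pts = spec.point_positions()
    centers = np.broadcast_to(pts.mean(axis=0), (n_atoms, 3)).copy()
    centers[spec.masked_slots] = pts
    return centers


def anchor_positions(
    r_pred: np.ndarray,
    spec: ConstraintSpec,
    t: int,
    sched: ScheduleSpec,
    ref_positions: np.ndarray | None = None,
) -> np.ndarray:
    """Blend masked slots toward their pharmacophore points.

    Masked row i becomes ``(1 - gamma_t) * r_pred_i + gamma_t * p_i``;
    unmasked rows are returned bit-identical.  ``ref_positions`` overrides the
    point coordinates (used by the noised-reference ablation); by default the
    original, un-noised coordinates are used.
    """
    if spec.n_points == 0:
        return r_pred
    g = sched.gamma_t(t)
    p = spec.point_positions() if ref_positions is None else np.asarray(ref_positions)
    out = r_pred.copy()
    slots = spec.masked_slots
    out[slots] = (1.0 - g) * r_pred[slots] + g * p
    return out


def protein_surface(r: np.ndarray, ctx: ProteinContext) -> np.ndarray | float:
    """Smoothed distance to the protein surface.

    ``S(r) = -sigma * log sum_j exp(-||r - a_j|| / sigma)`` — a soft minimum
    over protein-atom distances: always <= the true minimum distance and
    converging to it as sigma -> 0.
    """
    r = np.asarray(r, dtype=float)
    single = r.ndim == 1
    pts = np.atleast_2d(r)
    d = np.linalg.norm(pts[:, None, :] - ctx.atom_positions[None, :, :], axis=-1)
    s = -ctx.sigma * logsumexp(-d / ctx.sigma, axis=1)
    return float(s[0]) if single else s


def clash_loss(R: np.ndarray, ctx: ProteinContext) -> float:
    """Hinge-squared clash penalty: sum_i max(0, d_clash - S(r_i))^2."""
    s = np.atleast_1d(protein_surface(R, ctx))
    h = np.maximum(0.0, ctx.clash_threshold - s)
    return float(np.sum(h ** 2))


def clash_gradient(R: np.ndarray, ctx: ProteinContext) -> np.ndarray:
    """Analytic gradient of :func:`clash_loss` with respect to R (N x 3).

    Rows of atoms at or beyond the clash threshold are exactly zero.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    diff = R[:, None, :] - ctx.atom_positions[None, :, :]          # N x P x 3
    d = np.linalg.norm(diff, axis=-1)                              # N x P
    d_safe = np.maximum(d, 1e-12)
    w = softmax(-d / ctx.sigma, axis=1)                            # N x P
    s = -ctx.sigma * logsumexp(-d / ctx.sigma, axis=1)             # N
    # grad S(r_i) = sum_j w_ij * (r_i - a_j) / d_ij
    grad_s = np.einsum("np,npk->nk", w / d_safe, diff)
    h = np.maximum(0.0, ctx.clash_threshold - s)                   # N
    return (-2.0 * h)[:, None] * grad_s


def guided_step(
    out: DenoiserOutput,
    R_t: np.ndarray,
    ctx: ProteinContext | None,
    cfg: GuidanceConfig,
    sched: ScheduleSpec,
    t: int,
    rng: np.random.Generator,
    eps: np.ndarray | None = None,
    add_noise: bool = True,
) -> np.ndarray:
    """Sample positions from ``Normal(mu - lambda * Sigma_t * grad L, Sigma_t I)``.

    The clash gradient is evaluated at ``R_t`` (or at ``mu`` with
    ``grad_at='mean'``).  With ``add_noise=False`` (or Sigma_t = 0) the shifted
    mean is returned exactly.
    """
    sigma_sq = sched.sigma_sq_t(t)
    mean = out.mu
    if cfg.lam > 0 and ctx is not None:
        at = R_t if cfg.grad_at == "sample" else out.mu
        mean = mean - cfg.lam * sigma_sq * clash_gradient(at, ctx)
    if not add_noise or sigma_sq == 0.0:
        return mean
    if eps is None:
        eps = rng.standard_normal(mean.shape)
    return mean + math.sqrt(sigma_sq) * eps


def clamp_types(
    type_sample: np.ndarray,
    spec: ConstraintSpec,
    vocabulary: tuple[str, ...],
) -> np.ndarray:
    """Overwrite masked slots with the user-fixed element indices."""
    if spec.fixed_atom_types is None:
        return type_sample
    out = np.asarray(type_sample).copy()
    for slot, elem in zip(spec.masked_slots, spec.fixed_atom_types):
        if elem not in vocabulary:
            raise ConfigError(
                f"fixed atom type {elem!r} not in denoiser vocabulary {vocabulary}")
        out[slot] = vocabulary.index(elem)
    return out


# ---------------------------------------------------------------------------
# Full reverse trajectory and sampling

EpsFn = Callable[[tuple, np.random.Generator], np.ndarray]


def _default_eps(shape: tuple, rng: np.random.Generator) -> np.ndarray:
    return rng.standard_normal(shape)


def reverse_trajectory(
    denoiser: DenoiserInterface,
    spec: ConstraintSpec,
    ctx: ProteinContext | None,
    cfg: GuidanceConfig,
    sched: ScheduleSpec,
    n_atoms: int,
    rng: np.random.Generator,
    eps_fn: EpsFn = _default_eps,
    pocket_center: np.ndarray | None = None,
) -> tuple[Molecule3D, list[float]]:
    """Run one full guided reverse trajectory and return the final pose.

    Per step: denoise -> guidance shift -> sample -> anchor -> clamp types.
    Atom types and bonds take the modal category of the denoiser's logits
    (exact for one-hot logits); bond predictions are used unchanged.
    ``eps_fn`` supplies every Gaussian draw, enabling exact equivariance
    tests.  Returns the molecule and the clash-loss trace (one value per
    step; zeros when no protein context is given).
    """
    vocab = denoiser.vocabulary()
    init_mode = ("pure_random" if cfg.init_mode == "pure_random" else "around_points")
    if init_mode == "around_points" and spec.n_points == 0:
        warnings.warn("empty constraint spec: falling back to pure_random init",
                      stacklevel=2)
        init_mode = "pure_random"
    centers = _init_centers(spec, n_atoms, init_mode, pocket_center)
    R = centers + cfg.init_spread * eps_fn((n_atoms, 3), rng)

    types = np.zeros(n_atoms, dtype=int)
    types = clamp_types(types, spec, vocab)
    bonds = np.zeros((n_atoms, n_atoms), dtype=int)
    p_hat = spec.point_positions()
    losses: list[float] = []

    for t in range(sched.T, 0, -1):
        out = denoiser.denoise(R, types, bonds, t)
        R_next = guided_step(out, R, ctx, cfg, sched, t, rng,
                             eps=eps_fn((n_atoms, 3), rng) if t > 1 else None,
                             add_noise=t > 1)
        if spec.n_points and cfg.init_mode == "noised_reference" and t > 1:
            ab = sched.alpha_bar_t(t - 1)
            ref = (math.sqrt(ab) * p_hat
                   + math.sqrt(max(1.0 - ab, 0.0)) * eps_fn(p_hat.shape, rng))
        else:
            ref = None
        R = anchor_positions(R_next, spec, t, sched, ref_positions=ref)
        types = clamp_types(np.argmax(out.type_logits, axis=1), spec, vocab)
        bond_codes = np.argmax(out.bond_logits, axis=2)
        bonds = np.triu(bond_codes, 1)
        bonds = bonds + bonds.T
        losses.append(clash_loss(R, ctx) if ctx is not None else 0.0)

    mol = Molecule3D([vocab[i] for i in types], R, bonds, name="generated")
    return mol, losses


def _attempt_rng(seed: int, ligand: int, attempt: int) -> np.random.Generator:
    """Independent, reproducible stream per (ligand, attempt) via seed splitting."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(ligand, attempt))
    return np.random.Generator(np.random.PCG64(ss))


def sample(
    denoiser: DenoiserInterface,
    spec: ConstraintSpec,
    ctx: ProteinContext | None,
    cfg: GuidanceConfig,
    sched: ScheduleSpec | None = None,
    n_ligands: int = 1,
    n_atoms: int | None = None,
    eps_fn: EpsFn = _default_eps,
    pocket_center: np.ndarray | None = None,
) -> GenerationReport:
    """Generate ``n_ligands`` poses with the retry policy.

    Each requested ligand gets up to ``cfg.max_attempts`` full reverse
    trajectories; the first pose satisfying the pharmacophore spec is
    accepted.  All randomness flows from ``cfg.seed`` through a counter-based
    splitting scheme, so every (ligand, attempt) pair is independently
    reproducible.
    """
    if sched is None:
        sched = denoiser.schedule()
    if spec.fixed_atom_types is not None:
        vocab = denoiser.vocabulary()
        bad = [e for e in spec.fixed_atom_types if e not in vocab]
        if bad:
            raise ConfigError(f"fixed types {bad} not in denoiser vocabulary {vocab}")
    if n_atoms is None:
        n_atoms = max(len(spec.mask), spec.n_points)
    report = GenerationReport(requested=n_ligands)
    for lig in range(n_ligands):
        records: list[AttemptRecord] = []
        used = 0
        for attempt in range(cfg.max_attempts):
            rng = _attempt_rng(cfg.seed, lig, attempt)
            mol, losses = reverse_trajectory(
                denoiser, spec, ctx, cfg, sched, n_atoms, rng,
                eps_fn=eps_fn, pocket_center=pocket_center)
            used += 1
            if spec.n_points:
                ok, sat_report = satisfaction(mol, spec)
            else:
                ok, sat_report = True, []
            records.append(AttemptRecord(
                accepted=bool(ok),
                satisfaction_report=sat_report,
                clash_loss_final=losses[-1] if losses else 0.0,
                clash_loss_max=max(losses) if losses else 0.0,
            ))
            if ok:
                report.accepted.append(mol)
                break
        report.attempts_used.append(used)
        report.attempt_log.append(records)
    return report
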