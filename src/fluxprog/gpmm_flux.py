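"""Per-sample flux estimation.

Pipeline per sample: FPKM expression -> relative protein abundance ->
enzyme-capacity flux bounds (vmax = kcat x abundance) -> FBA with a
biomass + ATP-demand objective -> hit-and-run sampling of the feasible
polytope restricted to near-optimal objective values -> mean sampled flux.

All fluxes are in µmol/min/L; kcat values are per-minute turnover numbers.
The bridge between relative abundance and absolute capacity is a single
``scale`` factor in :class:`GpmmConfig`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import linprog

from .errors import ConfigError, InfeasibleError, ValidationError
from .network_io import MetabolicNetwork, evaluate_gpr, parse_gpr

logger = logging.getLogger(__name__)

__all__ = [
    "GpmmConfig",
    "FbaResult",
    "validate_expression",
    "estimate_protein_abundance",
    "read_kinetics_tsv",
    "compute_bounds",
    "fba",
    "sample_fluxes",
    "essential_reactions",
    "gpmm_flux_matrix",
]

FEAS_TOL = 1e-6


@dataclass
class GpmmConfig:
    """Settings for the flux-estimation stage."""

    biomass_reaction_id: str = "biomass"
    atp_demand_reaction_id: str = "DM_atp"
    objective_weights: tuple[float, float] = (1.0, 1.0)  # (biomass, ATP)
    optimum_fraction: float = 0.9
    n_mcmc_samples: int = 1000
    warmup_points: int = 1000  # adaptation needs ~10 rounds of 100 steps
    thinning: int = 10
    random_seed: int = 0
    flux_unit: str = "µmol/min/L"
    abundance_model: str = "power"
    abundance_params: dict = field(default_factory=lambda: {"alpha": 1.0})
    scale: float = 1.0
    default_kcat: float | str = "median"  # constant or "median" of the table
    missing_gene: str = "median"  # median | zero | skip-rule

    def __post_init__(self):
        if not (0.0 < self.optimum_fraction <= 1.0):
            raise ConfigError("optimum_fraction must be in (0, 1]")
        if self.n_mcmc_samples < 1:
            raise ConfigError("n_mcmc_samples must be >= 1")
        if self.scale <= 0:
            raise ConfigError("scale must be positive")
        if self.missing_gene not in ("median", "zero", "skip-rule"):
            raise ConfigError(f"unknown missing_gene policy {self.missing_gene!r}")

    def objective(self, network: MetabolicNetwork) -> dict[str, float]:
        w_bio, w_atp = self.objective_weights
        obj: dict[str, float] = {}
        rids = set(network.reaction_ids)
        if self.biomass_reaction_id in rids and w_bio:
            obj[self.biomass_reaction_id] = w_bio
        if self.atp_demand_reaction_id in rids and w_atp:
            obj[self.atp_demand_reaction_id] = w_atp
        if not obj:
            obj = dict(network.objective)
        if not obj:
            raise ConfigError("no objective reactions found in network")
        return obj


# ---------------------------------------------------------------------------
# Expression -> protein abundance
# ---------------------------------------------------------------------------

def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check a gene x sample FPKM table against its invariants."""
    if expr.index.has_duplicates:
        raise ValidationError("duplicate gene ids in expression matrix")
    if expr.columns.has_duplicates:
        raise ValidationError("duplicate sample ids in expression matrix")
    if (expr.to_numpy() < 0).any():
        raise ValidationError("expression matrix contains negative entries")
    return expr


def _power_law(expr: pd.DataFrame, alpha: float = 1.0) -> pd.DataFrame:
    return expr.pow(alpha)


ABUNDANCE_MODELS: dict[str, Callable[..., pd.DataFrame]] = {
    "power": _power_law,
    "identity": lambda expr: expr.copy(),
}


def estimate_protein_abundance(
    expr: pd.DataFrame, model: str = "power", **params
) -> pd.DataFrame:
    """Map FPKM to relative protein abundance with a pluggable model.

    The default is the power law ``abundance = FPKM ** alpha`` with
    ``alpha = 1`` (identity).  Register alternatives in
    :data:`ABUNDANCE_MODELS`.
    """
    validate_expression(expr)
    try:
        fn = ABUNDANCE_MODELS[model]
    except KeyError:
        raise ConfigError(
            f"unknown abundance model {model!r}; known: {sorted(ABUNDANCE_MODELS)}"
        ) from None
    out = fn(expr, **params)
    if (out.to_numpy() < 0).any():
        raise ValidationError("abundance model produced negative values")
    return out


# ---------------------------------------------------------------------------
# Kinetics and enzyme bounds
# ---------------------------------------------------------------------------

def read_kinetics_tsv(path) -> pd.DataFrame:
    """Read a kinetics table TSV (reaction_id, kcat_f, kcat_b[, source])."""
    df = pd.read_csv(path, sep="\t")
    required = {"reaction_id", "kcat_f", "kcat_b"}
    if not required.issubset(df.columns):
        raise ValidationError(f"kinetics table must have columns {sorted(required)}")
    if "source" not in df.columns:
        df["source"] = "measured"
    df = df.set_index("reaction_id")
    if (df["kcat_f"] <= 0).any() or (df["kcat_b"] <= 0).any():
        raise ValidationError("kcat values must be positive")
    return df


def compute_bounds(
    network: MetabolicNetwork,
    abundance: Mapping[str, float],
    kinetics: pd.DataFrame | Mapping[str, tuple[float, float]],
    scale: float = 1.0,
    default_kcat: float | str = "median",
    missing_gene: str = "median",
) -> tuple[np.ndarray, np.ndarray]:
    """Enzyme-capacity bounds for one sample, intersected with model bounds.

    For each reaction with a GPR rule: ``ub = scale * kcat_f * E`` and, if
    reversible, ``lb = -scale * kcat_b * E`` where E is the rule evaluated
    over ``abundance``.  Reactions with an empty rule keep model defaults.
    """
    if scale <= 0:
        raise ConfigError("scale must be positive")

    if isinstance(kinetics, pd.DataFrame):
        kin_f = kinetics["kcat_f"].to_dict()
        kin_b = kinetics["kcat_b"].to_dict()
    else:
        kin_f = {k: v[0] for k, v in kinetics.items()}
        kin_b = {k: v[1] for k, v in kinetics.items()}
    if default_kcat == "median":
        all_kcats = list(kin_f.values()) + list(kin_b.values())
        default_kcat = float(np.median(all_kcats)) if all_kcats else 1.0
    default_kcat = float(default_kcat)

    if missing_gene == "median":
        vals = np.asarray(list(abundance.values()), dtype=float)
        missing_value: float | None = float(np.median(vals)) if vals.size else 0.0
    elif missing_gene == "zero":
        missing_value = 0.0
    else:  # skip-rule: reactions whose rule has a missing gene keep defaults
        missing_value = None

    n = len(network.reactions)
    lb = np.empty(n)
    ub = np.empty(n)
    for j, rxn in enumerate(network.reactions):
        lb[j], ub[j] = rxn.lb, rxn.ub
        tree = parse_gpr(rxn.gpr)
        if tree is None:
            continue
        if missing_gene == "skip-rule" and not (rxn.genes() <= set(abundance)):
            continue
        enzyme = evaluate_gpr(tree, abundance, missing=missing_value)
        kf = kin_f.get(rxn.id, default_kcat)
        kb = kin_b.get(rxn.id, default_kcat)
        ub[j] = min(rxn.ub, scale * kf * enzyme)
        if rxn.reversible:
            lb[j] = max(rxn.lb, -scale * kb * enzyme)
        else:
            lb[j] = max(rxn.lb, 0.0)
        if lb[j] > ub[j]:  # can only happen via model defaults; clamp
            lb[j] = ub[j]
    return lb, ub


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

@dataclass
class FbaResult:
    fluxes: pd.Series
    objective_value: float


def _objective_vector(network: MetabolicNetwork, objective: Mapping[str, float]) -> np.ndarray:
    idx = {rid: j for j, rid in enumerate(network.reaction_ids)}
    w = np.zeros(len(idx))
    for rid, weight in objective.items():
        w[idx[rid]] = weight
    return w


def fba(
    network: MetabolicNetwork,
    lb: np.ndarray | None = None,
    ub: np.ndarray | None = None,
    objective: Mapping[str, float] | None = None,
) -> FbaResult:
    """Maximize ``w'v`` subject to ``S v = 0`` and ``lb <= v <= ub``.

    Raises :class:`InfeasibleError` naming the closed exchange reactions
    when the constraint set is empty.
    """
    S = network.stoichiometric_matrix()
    n = S.shape[1]
    if lb is None:
        lb = np.array([r.lb for r in network.reactions])
    if ub is None:
        ub = np.array([r.ub for r in network.reactions])
    if objective is None:
        objective = network.objective
    w = _objective_vector(network, objective)

    res = linprog(
        c=-w,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2:
        closed = [
            r.id
            for j, r in enumerate(network.reactions)
            if r.is_exchange and lb[j] >= 0
        ]
        raise InfeasibleError(
            "FBA constraint set is infeasible; exchanges closed for uptake: "
            f"{closed}"
        )
    if not res.success:
        raise InfeasibleError(f"LP solver failed: {res.message}")
    fluxes = pd.Series(res.x, index=network.reaction_ids, name="flux")
    return FbaResult(fluxes=fluxes, objective_value=float(-res.fun))


# ---------------------------------------------------------------------------
# Hit-and-run sampling
# ---------------------------------------------------------------------------

def _polytope_basis(S: np.ndarray):
    """Null-space basis of S; points v = v0 + N t satisfy S v = S v0."""
    if S.size == 0:
        return np.eye(S.shape[1])
    return null_space(S)


def sample_fluxes(
    network: MetabolicNetwork,
    lb: np.ndarray | None = None,
    ub: np.ndarray | None = None,
    config: GpmmConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.Series]:
    """Sample the near-optimal flux polytope and return (points, mean flux).

    The polytope is ``{v : S v = 0, lb <= v <= ub, w'v >= gamma * opt}``,
    parametrized on the null space of S so steady state holds exactly for
    every point.  The chain is hit-and-run started at the Chebyshev center,
    with directions drawn from the running point covariance during warmup
    (the artificial-centering device in distributional form: ACHR's
    point-minus-center directions have exactly the point covariance) and
    frozen afterwards so the uniform target is preserved.  Retained points
    satisfy all bounds within 1e-6 and are reproducible given the seed.
    """
    config = config or GpmmConfig()
    if rng is None:
        rng = np.random.default_rng(config.random_seed)
    if lb is None:
        lb = np.array([r.lb for r in network.reactions])
    if ub is None:
        ub = np.array([r.ub for r in network.reactions])
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)

    try:
        objective = config.objective(network)
    except ConfigError:
        objective = {}  # unconstrained sampling of the full polytope
    w = _objective_vector(network, objective)
    try:
        base = fba(network, lb, ub, objective)
    except InfeasibleError:
        raise InfeasibleError(
            "flux polytope is empty; check medium and enzyme bounds"
        ) from None
    opt = base.objective_value
    v0 = base.fluxes.to_numpy()

    S = network.stoichiometric_matrix()
    N = _polytope_basis(S)
    d = N.shape[1]
    reaction_ids = network.reaction_ids

    # inequalities A t <= b in null-space coordinates
    rows = [N, -N]
    rhs = [ub - v0, v0 - lb]
    if objective and opt > FEAS_TOL and config.optimum_fraction > 0:
        rows.append(-(w @ N)[None, :])
        rhs.append(np.array([w @ v0 - config.optimum_fraction * opt]))
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    b = np.maximum(b, 0.0)  # v0 is feasible; clip tiny negative slack

    if d == 0:
        points_v = np.tile(v0, (config.n_mcmc_samples, 1))
        mean = pd.Series(v0, index=reaction_ids, name="mean_flux")
        return points_v, mean

    A = np.ascontiguousarray(A)
    t = _chebyshev_center(A, b)
    shape_l = np.eye(d)

    def walk(state, n_steps, shape):
        traj = np.empty((n_steps, d))
        state = _hr_kernel(
            A, b, state.copy(), np.ascontiguousarray(shape),
            rng.standard_normal((n_steps, d)), rng.random(n_steps), traj,
        )
        return state, traj

    # warmup in adaptation rounds: each round re-estimates the point
    # covariance used to draw directions (artificial centering in
    # distributional form); frozen before the retained phase
    warmup_traj: list[np.ndarray] = []
    if config.warmup_points > 0:
        n_rounds = max(1, min(10, config.warmup_points // 100))
        per_round = config.warmup_points // n_rounds
        done = 0
        for r in range(n_rounds):
            steps = per_round if r < n_rounds - 1 else config.warmup_points - done
            if steps <= 0:
                break
            t, traj = walk(t, steps, shape_l)
            warmup_traj.append(traj)
            done += steps
            pts = np.vstack(warmup_traj)
            pts = pts[len(pts) // 3 :]  # drop the earliest third
            if len(pts) > d + 2:
                cov = np.atleast_2d(np.cov(pts.T))
                cov += 1e-10 * max(1.0, np.trace(cov)) * np.eye(d)
                try:
                    shape_l = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass

    n_main = config.n_mcmc_samples * config.thinning
    t, traj = walk(t, n_main, shape_l)
    retained = traj[config.thinning - 1 :: config.thinning][: config.n_mcmc_samples]
    if len(retained) < config.n_mcmc_samples:  # short chains: pad with last state
        pad = np.tile(t, (config.n_mcmc_samples - len(retained), 1))
        retained = np.vstack([retained, pad])

    points_v = v0[None, :] + retained @ N.T
    mean = pd.Series(points_v.mean(axis=0), index=reaction_ids, name="mean_flux")
    return points_v, mean


def _hr_kernel(A, b, t, L, normals, uniforms, traj):
    """Hit-and-run walk: ``n_steps`` chord draws with directions L @ N(0, I).

    Mutates ``t`` and fills ``traj`` with the state after every step.
    Compiled with numba when available; the pure-Python path is identical.
    """
    n_steps, d = normals.shape
    m = A.shape[0]
    slack = b - A @ t
    for i in range(m):
        if slack[i] < 0.0:
            slack[i] = 0.0
    for s in range(n_steps):
        direction = L @ normals[s]
        nrm = 0.0
        for i in range(d):
            nrm += direction[i] * direction[i]
        nrm = math.sqrt(nrm)
        if nrm < 1e-12:
            traj[s] = t
            continue
        for i in range(d):
            direction[i] /= nrm
        proj = A @ direction
        alpha_max = 1e300
        alpha_min = -1e300
        for i in range(m):
            p = proj[i]
            if p > 1e-12:
                r = slack[i] / p
                if r < alpha_max:
                    alpha_max = r
            elif p < -1e-12:
                r = slack[i] / p
                if r > alpha_min:
                    alpha_min = r
        # cap unbounded chords (possible only with infinite model bounds)
        if alpha_max > 1e299:
            alpha_max = 1e6
        if alpha_min < -1e299:
            alpha_min = -1e6
        if alpha_max - alpha_min > 1e-10:
            alpha = alpha_min + uniforms[s] * (alpha_max - alpha_min)
            for i in range(d):
                t[i] += alpha * direction[i]
            for i in range(m):
                slack[i] -= alpha * proj[i]
                if slack[i] < 0.0:
                    slack[i] = 0.0
        traj[s] = t
    return t


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _hr_kernel = njit(cache=False)(_hr_kernel)
except Exception:  # pragma: no cover
    logger.info("numba unavailable; hit-and-run runs in pure Python")


def _chebyshev_center(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Center of the largest inscribed ball of {A t <= b}; a well-centered
    chain start.  Falls back to the origin (always feasible here)."""
    m, d = A.shape
    norms = np.linalg.norm(A, axis=1)
    c = np.zeros(d + 1)
    c[-1] = -1.0
    res = linprog(
        c,
        A_ub=np.hstack([A, norms[:, None]]),
        b_ub=b,
        bounds=[(-1e7, 1e7)] * d + [(0.0, 1e7)],
        method="highs",
    )
    if res.success and np.all(A @ res.x[:-1] <= b + 1e-9):
        return res.x[:-1]
    return np.zeros(d)


# ---------------------------------------------------------------------------
# Essentiality
# ---------------------------------------------------------------------------

def essential_reactions(
    network: MetabolicNetwork,
    lb: np.ndarray | None = None,
    ub: np.ndarray | None = None,
    objective: Mapping[str, float] | None = None,
    threshold_fraction: float = 1e-6,
) -> list[str]:
    """Reactions whose knockout drops the FBA optimum below
    ``threshold_fraction`` x baseline.  Requires a positive baseline."""
    if lb is None:
        lb = np.array([r.lb for r in network.reactions])
    if ub is None:
        ub = np.array([r.ub for r in network.reactions])
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if objective is None:
        objective = network.objective
    baseline = fba(network, lb, ub, objective).objective_value
    if baseline <= FEAS_TOL:
        raise ValidationError("baseline FBA optimum is 0; essentiality undefined")
    essential = []
    for j, rxn in enumerate(network.reactions):
        lb_j, ub_j = lb[j], ub[j]
        if lb_j > 0 or ub_j < 0:
            ko_lb, ko_ub = lb.copy(), ub.copy()
            ko_lb[j] = ko_ub[j] = 0.0
            # forcing through-zero on a strictly signed reaction
            try:
                opt = fba(network, ko_lb, ko_ub, objective).objective_value
            except InfeasibleError:
                opt = 0.0
        else:
            ko_lb, ko_ub = lb.copy(), ub.copy()
            ko_lb[j] = ko_ub[j] = 0.0
            try:
                opt = fba(network, ko_lb, ko_ub, objective).objective_value
            except InfeasibleError:
                opt = 0.0
        if opt < threshold_fraction * baseline:
            essential.append(rxn.id)
    return essential


# ---------------------------------------------------------------------------
# Cohort-level driver
# ---------------------------------------------------------------------------

def gpmm_flux_matrix(
    network: MetabolicNetwork,
    expression: pd.DataFrame,
    kinetics: pd.DataFrame | Mapping[str, tuple[float, float]],
    config: GpmmConfig | None = None,
) -> pd.DataFrame:
    """Mean sampled flux for every reaction in every sample.

    Returns a reaction x sample DataFrame (the pipeline's FluxMatrix).
    Sampling is seeded per sample from ``config.random_seed`` so columns
    are reproducible and independent of cohort ordering.
    """
    config = config or GpmmConfig()
    abundance = estimate_protein_abundance(
        expression, config.abundance_model, **config.abundance_params
    )
    columns = {}
    seed_seq = np.random.SeedSequence(config.random_seed)
    for sample in expression.columns:
        col_abund = abundance[sample].to_dict()
        lb, ub = compute_bounds(
            network,
            col_abund,
            kinetics,
            scale=config.scale,
            default_kcat=config.default_kcat,
            missing_gene=config.missing_gene,
        )
        # stable per-sample stream: independent of cohort ordering and of
        # Python's per-process hash randomization
        import hashlib

        key = int.from_bytes(hashlib.sha256(str(sample).encode()).digest()[:4], "big")
        child = np.random.SeedSequence(entropy=seed_seq.entropy, spawn_key=(key,))
        rng = np.random.default_rng(child)
        _, mean = sample_fluxes(network, lb, ub, config, rng=rng)
        columns[sample] = mean
    flux = pd.DataFrame(columns)
    flux.index.name = "reaction_id"
    return flux
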