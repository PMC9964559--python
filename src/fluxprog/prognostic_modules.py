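"""Prognosis-associated flux analysis.

Four stages over a reaction x sample flux matrix:

1. per-reaction median-split log-rank screening (``find_prognostic_reactions``);
2. grouping of significant reactions into correlation modules
   (``extract_modules`` — graph of |Spearman rho| > threshold, non-singular
   nodes, connected components);
3. moderated-t differential flux between two sample groups
   (``differential_flux`` — empirical-Bayes variance shrinkage);
4. pathway-level weighted differential-abundance scores (``wda_scores``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import spearmanr, t as t_dist

from .errors import DegenerateSplitError, ValidationError
from .survival_stats import SurvivalRecord, cox_univariate, logrank, median_split

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionPrognosis",
    "FluxModule",
    "find_prognostic_reactions",
    "extract_modules",
    "differential_flux",
    "wda_scores",
]


# ---------------------------------------------------------------------------
# Prognostic reactions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionPrognosis:
    reaction_id: str
    logrank_p: float
    direction: int  # +1: high flux -> longer survival; -1: shorter
    log_hr: float


def find_prognostic_reactions(
    flux: pd.DataFrame,
    surv: Sequence[SurvivalRecord],
    alpha: float = 0.01,
) -> list[ReactionPrognosis]:
    """Reactions whose median-split flux groups differ in survival.

    For each reaction: median-split samples by flux, log-rank test, keep
    p < alpha (strict).  Direction comes from the sign of the Cox log
    hazard ratio of the high group: positive log-HR means high flux is
    harmful (direction -1).  Constant-flux or degenerate reactions are
    skipped and logged.
    """
    results: list[ReactionPrognosis] = []
    n_skipped = 0
    for rid, row in flux.iterrows():
        values = row.to_dict()
        try:
            labels = median_split(values)
        except (DegenerateSplitError, ValidationError):
            n_skipped += 1
            continue
        if len(set(labels.values())) < 2:
            n_skipped += 1
            continue
        try:
            lr = logrank(labels, surv)
        except ValidationError:
            n_skipped += 1
            continue
        if not (lr.p_value < alpha):
            continue
        try:
            cox = cox_univariate(labels, surv)
            log_hr = cox.log_hr
        except ValidationError:
            log_hr = lr.observed_minus_expected  # same sign as the hazard effect
        direction = -1 if log_hr > 0 else 1
        results.append(ReactionPrognosis(str(rid), lr.p_value, direction, float(log_hr)))
    if n_skipped:
        logger.info("find_prognostic_reactions: skipped %d degenerate reactions", n_skipped)
    return results


# ---------------------------------------------------------------------------
# Correlation modules
# ---------------------------------------------------------------------------

@dataclass
class FluxModule:
    module_id: str
    members: list[str]
    direction: int
    representative: str | None = None
    mixed_direction: bool = False


def _correlation_matrix(flux: pd.DataFrame, method: str) -> np.ndarray:
    if method == "spearman":
        rho = spearmanr(flux.to_numpy(), axis=1).statistic
        if np.ndim(rho) == 0:  # spearmanr collapses 2x2
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        return np.asarray(rho)
    if method == "pearson":
        return np.corrcoef(flux.to_numpy())
    raise ValidationError(f"unknown correlation method {method!r}")


def extract_modules(
    flux: pd.DataFrame,
    prognosis: Sequence[ReactionPrognosis],
    r_threshold: float = 0.8,
    min_neighbors: int = 1,
    method: str = "spearman",
) -> list[FluxModule]:
    """Group prognostic reactions into correlation modules.

    Builds a graph over the prognostic reactions with an edge whenever
    |correlation| > ``r_threshold``, drops nodes with fewer than
    ``min_neighbors`` edges (the non-singularity rule), and reports the
    connected components of what remains as modules.  Module direction is
    the majority member direction; mixed components are flagged.
    Deterministic: module ids follow the sorted id of each component's
    first member.
    """
    prog_ids = sorted({p.reaction_id for p in prognosis} & set(map(str, flux.index)))
    if len(prog_ids) < 2:
        return []
    direction = {p.reaction_id: p.direction for p in prognosis}
    pvals = {p.reaction_id: p.logrank_p for p in prognosis}
    sub = flux.loc[prog_ids]
    rho = _correlation_matrix(sub, method)

    graph = nx.Graph()
    graph.add_nodes_from(prog_ids)
    n = len(prog_ids)
    for i in range(n):
        for j in range(i + 1, n):
            r = rho[i, j]
            if np.isfinite(r) and abs(r) > r_threshold:
                graph.add_edge(prog_ids[i], prog_ids[j])

    keep = [node for node in graph if graph.degree(node) >= min_neighbors]
    dropped = sorted(set(prog_ids) - set(keep))
    if dropped:
        logger.info(
            "extract_modules: dropped %d singular reactions (< %d correlated partners): %s",
            len(dropped), min_neighbors, dropped,
        )
    graph = graph.subgraph(keep)

    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    modules: list[FluxModule] = []
    for k, members in enumerate(components, start=1):
        dirs = [direction[m] for m in members]
        majority = 1 if sum(dirs) >= 0 else -1
        mixed = len(set(dirs)) > 1
        if mixed:
            # expected whenever an uptake exchange (negative flux) joins its
            # chain; the flag is carried on the module itself
            logger.info("module %d has mixed member directions: %s", k, members)
        aligned = [m for m in members if direction[m] == majority]
        rep = min(aligned or members, key=lambda m: (pvals[m], m))
        modules.append(
            FluxModule(
                module_id=f"M{k}",
                members=members,
                direction=majority,
                representative=rep,
                mixed_direction=mixed,
            )
        )
    return modules


# ---------------------------------------------------------------------------
# Moderated-t differential flux
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse chi-square prior to observed variances.

    Returns (prior df d0, prior variance s0^2).  d0 = inf means complete
    shrinkage (all variances equal within noise); d0 = 0 means no pooling
    information.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2) + math.log(df / 2)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, df / 2))
    if evar <= 0:
        return math.inf, float(math.exp(emean))
    d0 = 2 * _trigamma_inverse(evar)
    s0_sq = math.exp(emean + float(digamma(d0 / 2)) - math.log(d0 / 2))
    return d0, s0_sq


def differential_flux(
    flux: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.01,
    prior_df: float | None = None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Two-group moderated-t differential analysis of fluxes.

    Reactions whose values share a single sign across samples are analyzed
    as log2(|flux| + pseudocount); sign-mixed reactions are analyzed on the
    raw scale and flagged in the ``scale`` column.  Residual variances are
    shrunk toward a moment-matched prior (empirical Bayes); ``prior_df=0``
    disables shrinkage and recovers the ordinary two-sample t-test.

    The log2 fold change (``log2fc``) is mean(high) - mean(low) for
    high/low groups, or second-sorted-level minus first otherwise.
    """
    samples = [s for s in flux.columns if s in groups]
    levels = sorted({groups[s] for s in samples})
    if len(levels) != 2:
        raise ValidationError(f"expected 2 group levels, got {levels}")
    if levels == ["high", "low"]:
        levels = ["low", "high"]
    g0 = [s for s in samples if groups[s] == levels[0]]
    g1 = [s for s in samples if groups[s] == levels[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValidationError("need at least 2 samples per group")

    x = flux[g0 + g1].to_numpy(dtype=float)
    n0, n1 = len(g0), len(g1)

    pos = (x > 0).all(axis=1)
    neg = (x < 0).all(axis=1)
    consistent = pos | neg
    y = np.where(
        consistent[:, None], np.log2(np.abs(x) + pseudocount, where=consistent[:, None] | (x != 0), out=np.zeros_like(x)), x
    )
    scale = np.where(consistent, "log2", "raw")

    m0 = y[:, :n0].mean(axis=1)
    m1 = y[:, n0:].mean(axis=1)
    diff = m1 - m0
    ss = y[:, :n0].var(axis=1, ddof=1) * (n0 - 1) + y[:, n0:].var(axis=1, ddof=1) * (n1 - 1)
    df_resid = n0 + n1 - 2
    s2 = ss / df_resid
    se_factor = math.sqrt(1 / n0 + 1 / n1)

    if prior_df is None:
        d0, s0_sq = _fit_variance_prior(s2, df_resid)
        if not np.isfinite(d0) and d0 != math.inf:
            d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_variance_prior(s2, df_resid) if d0 > 0 else (0.0, 0.0)

    if d0 == math.inf:
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
        logger.info("differential_flux: variance distribution degenerate; full shrinkage")
    elif d0 == 0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = diff / (np.sqrt(s2_post) * se_factor)
    tstat = np.where(np.isfinite(tstat), tstat, 0.0)
    if np.isinf(df_total):
        from scipy.stats import norm

        pvals = 2 * norm.sf(np.abs(tstat))
    else:
        pvals = 2 * t_dist.sf(np.abs(tstat), df=df_total)

    from statsmodels.stats.multitest import multipletests

    bh = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals

    out = pd.DataFrame(
        {
            "reaction_id": flux.index.astype(str),
            "log2fc": diff,
            "t_moderated": tstat,
            "p_value": pvals,
            "p_adj_bh": bh,
            "significant": pvals < alpha,
            "scale": scale,
            "prior_df": d0 if np.isfinite(d0) else np.inf,
        }
    ).set_index("reaction_id")
    return out


# ---------------------------------------------------------------------------
# WDA pathway scores
# ---------------------------------------------------------------------------

def wda_scores(
    diff: pd.DataFrame,
    subsystem_map: Mapping[str, str],
) -> pd.DataFrame:
    """Weighted differential-abundance score per subsystem (pathway).

    With T = total significant fluxes network-wide and, per pathway,
    n = member fluxes, k_up/k_down = significantly increased/decreased:

        Weight = (k_up + k_down) / T
        WDA    = 100 * Weight * (k_up - k_down) / n

    Reactions without a subsystem are excluded (with a warning) from both
    pathway membership and the network-wide denominator.  A pathway with no
    significant fluxes scores 0.
    """
    known = diff.index.astype(str).map(lambda r: r in subsystem_map)
    missing = sorted(diff.index[~known].astype(str))
    if missing:
        logger.warning("wda_scores: %d reactions lack a subsystem, excluded: %s",
                       len(missing), missing[:10])
    d = diff.loc[np.asarray(known)]
    subsystems = np.array([subsystem_map[str(r)] for r in d.index])

    total_sig = int(d["significant"].sum())
    rows = []
    for subsystem in sorted(set(subsystems)):
        sub = d.loc[subsystems == subsystem]
        n_fluxes = len(sub)
        sig = sub[sub["significant"]]
        n_up = int((sig["log2fc"] > 0).sum())
        n_down = int((sig["log2fc"] < 0).sum())
        if total_sig > 0:
            weight = (n_up + n_down) / total_sig
        else:
            weight = 0.0
        wda = 100.0 * weight * (n_up - n_down) / n_fluxes if n_fluxes else 0.0
        rows.append(
            {
                "subsystem": subsystem,
                "n_fluxes": n_fluxes,
                "n_increased": n_up,
                "n_decreased": n_down,
                "weight": weight,
                "wda": wda,
            }
        )
    return pd.DataFrame(rows).set_index("subsystem")
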