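"""Two-module concordant subtypes.

Combines two flux modules through independent median splits of their
representative reactions.  The "concordant good" class is high in the
positively-associated module and low in the negatively-associated one;
"concordant bad" is the exact complement; everything else is "other".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateSplitError, ValidationError
from .prognostic_modules import FluxModule, ReactionPrognosis
from .survival_stats import (
    CoxResult,
    SurvivalRecord,
    cox_univariate,
    km_median,
    logrank,
    median_split,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SubtypeAssignment",
    "select_representative",
    "assign_subtype",
    "scan_pairs",
    "summarize_subtype",
]

GOOD = "concordant_good"
BAD = "concordant_bad"
OTHER = "other"


@dataclass
class SubtypeAssignment:
    labels: dict[str, str]  # sample -> concordant_good | concordant_bad | other
    positive_representative: str
    negative_representative: str


def select_representative(
    module: FluxModule, prognosis: Sequence[ReactionPrognosis]
) -> str:
    """The member with the smallest log-rank p; ties break lexicographically.

    In mixed-direction modules (e.g. an uptake exchange whose negative flux
    mirrors its chain), only members sharing the module's majority direction
    are eligible, so the representative's orientation matches the module's.
    """
    if not module.members:
        raise ValidationError("module has no members")
    pvals = {p.reaction_id: p.logrank_p for p in prognosis}
    dirs = {p.reaction_id: p.direction for p in prognosis}
    aligned = [m for m in module.members if dirs.get(m, module.direction) == module.direction]
    candidates = aligned or list(module.members)
    return min(candidates, key=lambda m: (pvals.get(m, 1.0), m))


def assign_subtype(
    flux_pos: Mapping[str, float], flux_neg: Mapping[str, float]
) -> dict[str, str]:
    """Concordance labels from two independent median splits.

    good = high in ``flux_pos`` and low in ``flux_neg``; bad = the exact
    complement; remainder = other.
    """
    if set(flux_pos) != set(flux_neg):
        raise ValidationError("flux_pos and flux_neg must cover the same samples")
    split_pos = median_split(flux_pos)  # raises DegenerateSplitError if flat
    split_neg = median_split(flux_neg)
    out = {}
    for s in flux_pos:
        if split_pos[s] == "high" and split_neg[s] == "low":
            out[s] = GOOD
        elif split_pos[s] == "low" and split_neg[s] == "high":
            out[s] = BAD
        else:
            out[s] = OTHER
    return out


def _oriented_fluxes(
    module_a: FluxModule,
    module_b: FluxModule,
    flux: pd.DataFrame,
) -> tuple[pd.Series, pd.Series]:
    """Orient a module pair so the good pattern is well defined.

    Opposite directions: the +1 module plays the "positive" role.  Same
    direction: both modules play the positive role when direction is +1
    (good = high in both) and the negative role when -1 (good = low in
    both); this is encoded by negating one vector so the generic
    high-in-positive / low-in-negative rule applies.
    """
    rep_a = flux.loc[module_a.representative]
    rep_b = flux.loc[module_b.representative]
    if module_a.direction >= 0 and module_b.direction < 0:
        return rep_a, rep_b
    if module_a.direction < 0 and module_b.direction >= 0:
        return rep_b, rep_a
    if module_a.direction >= 0:  # both protective: good = high in both
        return rep_a, -rep_b
    return -rep_a, rep_b  # both harmful: good = low in both


def scan_pairs(
    modules: Sequence[FluxModule],
    flux: pd.DataFrame,
    surv: Sequence[SurvivalRecord],
    min_group_size: int = 5,
) -> pd.DataFrame:
    """Evaluate every module pair's concordant-class survival contrast.

    Returns a DataFrame ranked by log-rank p (ascending, ties broken by
    the pair id), one row per evaluated pair.  Pairs whose concordant
    classes fall below ``min_group_size`` are skipped and logged.
    """
    if len(modules) < 2:
        raise ValidationError("pair scan requires at least 2 modules")
    rows = []
    for mod_a, mod_b in combinations(modules, 2):
        pair_id = f"{mod_a.module_id}|{mod_b.module_id}"
        try:
            fpos, fneg = _oriented_fluxes(mod_a, mod_b, flux)
            labels = assign_subtype(fpos.to_dict(), fneg.to_dict())
        except (DegenerateSplitError, ValidationError) as exc:
            logger.info("scan_pairs: skipping %s (%s)", pair_id, exc)
            continue
        n_good = sum(1 for v in labels.values() if v == GOOD)
        n_bad = sum(1 for v in labels.values() if v == BAD)
        if min(n_good, n_bad) < min_group_size:
            logger.info(
                "scan_pairs: skipping %s (concordant class below %d samples)",
                pair_id, min_group_size,
            )
            continue
        concordant = {s: v for s, v in labels.items() if v != OTHER}
        try:
            lr = logrank(concordant, surv)
        except ValidationError as exc:
            logger.info("scan_pairs: skipping %s (%s)", pair_id, exc)
            continue
        try:
            cox = cox_univariate(
                {s: ("high" if v == GOOD else "low") for s, v in concordant.items()},
                surv,
            )
            hr = cox.hazard_ratio
        except ValidationError:
            hr = np.nan
        rows.append(
            {
                "pair": pair_id,
                "module_a": mod_a.module_id,
                "module_b": mod_b.module_id,
                "n_good": n_good,
                "n_bad": n_bad,
                "hazard_ratio": hr,
                "logrank_p": lr.p_value,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "pair", "module_a", "module_b", "n_good", "n_bad",
            "hazard_ratio", "logrank_p",
        ],
    )
    return df.sort_values(["logrank_p", "pair"], kind="mergesort").reset_index(drop=True)


def summarize_subtype(
    labels: Mapping[str, str], surv: Sequence[SurvivalRecord]
) -> dict:
    """Cohort-level summary of a concordant subtype assignment.

    Includes class sizes and frequencies, the good-vs-bad hazard ratio and
    log-rank p, Kaplan-Meier medians per class and for the rest of the
    cohort, and median-survival gains of the good class (percent).  Gains
    are ``None`` when a median is not reached.
    """
    n_total = len(labels)
    counts = {lab: sum(1 for v in labels.values() if v == lab) for lab in (GOOD, BAD, OTHER)}
    if counts[GOOD] == 0 or counts[BAD] == 0:
        raise ValidationError("both concordant classes must be non-empty")

    concordant = {s: v for s, v in labels.items() if v != OTHER}
    lr = logrank(concordant, surv)
    cox: CoxResult = cox_univariate(
        {s: ("high" if v == GOOD else "low") for s, v in concordant.items()}, surv
    )

    medians = km_median(dict(labels), surv)
    rest = {s: (GOOD if v == GOOD else "rest") for s, v in labels.items()}
    med_rest = km_median(rest, surv).get("rest")

    def gain(reference: float | None) -> float | None:
        good_med = medians.get(GOOD)
        if good_med is None or reference is None or reference == 0:
            logger.warning("summarize_subtype: median not reached; gain undefined")
            return None
        return (good_med - reference) / reference * 100.0

    return {
        "n": counts,
        "frequency": {lab: counts[lab] / n_total for lab in counts},
        "hazard_ratio": cox.hazard_ratio,
        "hr_ci": [cox.ci_lower, cox.ci_upper],
        "hr_divergent": cox.divergent,
        "logrank_p": lr.p_value,
        "median_survival": {**medians, "rest_of_cohort": med_rest},
        "median_gain_vs_bad_pct": gain(medians.get(BAD)),
        "median_gain_vs_rest_pct": gain(med_rest),
    }
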