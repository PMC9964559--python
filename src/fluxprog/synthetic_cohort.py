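"""Synthetic toy networks and cohorts with planted prognostic flux modules.

Every pipeline stage is testable offline: :func:`make_toy_network` builds a
small connected metabolic network of parallel enzymatic pathways feeding a
biomass reaction plus an ATP-demand chain; :func:`simulate_cohort` layers
on log-normal FPKM expression with latent-factor co-expression in the
planted pathways, a kinetics table, and exponential survival whose
log-hazard is linear in the planted latent activities, with uniform
censoring.

The planted structure (module membership, per-sample latent activities,
implied concordant subtype labels) is carried alongside the data so tests
can score recovery exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .network_io import MetabolicNetwork, Metabolite, Reaction
from .survival_stats import SurvivalRecord

__all__ = [
    "PlantedModule",
    "SyntheticSpec",
    "SyntheticCohort",
    "make_toy_network",
    "simulate_cohort",
    "ground_truth",
    "write_cohort",
]


@dataclass(frozen=True)
class PlantedModule:
    subsystem: str
    beta: float  # effect on log hazard per unit latent activity


@dataclass
class SyntheticSpec:
    n_samples: int = 150
    n_pathways: int = 4
    reactions_per_pathway: int = 3
    planted: list[PlantedModule] = field(
        default_factory=lambda: [PlantedModule("PW1", -0.7), PlantedModule("PW2", 0.7)]
    )
    loading: float = 0.95  # latent-factor loading in [0, 1]
    noise_sd: float = 0.1  # expression noise on the log scale
    baseline_hazard: float = 0.08  # events per month at latent activity 0
    censor_max: float = 120.0  # uniform censoring window (0, C_max] months
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 20:
            raise ValidationError("n_samples must be >= 20")
        if not (0.0 <= self.loading <= 1.0):
            raise ValidationError("loading must be in [0, 1]")
        for m in self.planted:
            if abs(m.beta) > 2:
                raise ValidationError("|beta| must be <= 2")
        names = {f"PW{i + 1}" for i in range(self.n_pathways)}
        for m in self.planted:
            if m.subsystem not in names:
                raise ValidationError(f"planted subsystem {m.subsystem!r} not generated")


@dataclass
class SyntheticCohort:
    network: MetabolicNetwork
    kinetics: pd.DataFrame
    expression: pd.DataFrame
    survival: list[SurvivalRecord]
    truth_members: dict[str, list[str]]  # subsystem -> planted reaction ids
    truth_z: pd.DataFrame  # planted subsystem x sample latent activities
    truth_subtype: dict[str, str]  # sample -> concordant_good/bad/other
    spec: SyntheticSpec


def make_toy_network(spec: SyntheticSpec) -> MetabolicNetwork:
    """A connected toy network with one enzymatic chain per pathway.

    Pathway i: EX_i (uptake) -> chain of enzymatic reactions -> terminal
    T_i, drained both by the shared biomass reaction (which consumes every
    pathway's terminal) and by a pathway-specific demand DM_i so chains can
    vary independently of biomass.  A separate maintenance chain produces
    atp for the ATP-demand reaction DM_atp.  The first pathway carries an
    OR and an AND rule for GPR coverage; every other enzymatic reaction has
    a single gene.
    """
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    genes: list[str] = []

    terminal_ids = []
    for i in range(1, spec.n_pathways + 1):
        pw = f"PW{i}"
        chain_mets = [f"m{i}_{j}" for j in range(spec.reactions_per_pathway + 1)]
        mets.extend(Metabolite(mid, compartment="c") for mid in chain_mets)
        rxns.append(
            Reaction(
                id=f"EX_{i}",
                stoichiometry={chain_mets[0]: -1.0},
                lb=-1000.0, ub=1000.0,
                subsystem=pw,
            )
        )
        for j in range(spec.reactions_per_pathway):
            gene = f"g{i}_{j}"
            if i == 1 and j == 0:
                gpr = f"({gene} or {gene}b)"
                genes.extend([gene, f"{gene}b"])
            elif i == 1 and j == 1:
                gpr = f"({gene} and {gene}b)"
                genes.extend([gene, f"{gene}b"])
            else:
                gpr = gene
                genes.append(gene)
            rxns.append(
                Reaction(
                    id=f"R{i}_{j}",
                    stoichiometry={chain_mets[j]: -1.0, chain_mets[j + 1]: 1.0},
                    lb=0.0, ub=1000.0,
                    gpr=gpr,
                    subsystem=pw,
                )
            )
        terminal = chain_mets[-1]
        terminal_ids.append(terminal)
        rxns.append(
            Reaction(
                id=f"DM_{i}",
                stoichiometry={terminal: -1.0},
                lb=0.0, ub=1000.0,
                subsystem=pw,
            )
        )

    # maintenance chain feeding the ATP demand
    mets.extend([Metabolite("atp_src", compartment="c"), Metabolite("atp", compartment="c")])
    genes.append("g_atp")
    rxns.extend(
        [
            Reaction(id="EX_atp_src", stoichiometry={"atp_src": -1.0},
                     lb=-1000.0, ub=1000.0, subsystem="maintenance"),
            Reaction(id="R_atp", stoichiometry={"atp_src": -1.0, "atp": 1.0},
                     lb=0.0, ub=1000.0, gpr="g_atp", subsystem="maintenance"),
            Reaction(id="DM_atp", stoichiometry={"atp": -1.0},
                     lb=0.0, ub=1000.0, subsystem="maintenance"),
        ]
    )
    rxns.append(
        Reaction(
            id="biomass",
            stoichiometry={t: -1.0 for t in terminal_ids},
            lb=0.0, ub=1000.0,
            subsystem="biomass",
        )
    )
    return MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective={"biomass": 1.0, "DM_atp": 1.0},
        id="toy",
    )


def simulate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate network + kinetics + expression + survival + ground truth.

    Expression: log-FPKM of gene g in sample s is mu_g + loading * z_ms +
    noise for genes of planted pathway m (mu_g ~ Normal(3, 1) fixed per
    gene), mu_g + noise otherwise; FPKM = exp.  Survival: T ~ Exponential
    with rate baseline_hazard * exp(sum_m beta_m z_ms), censored by
    U ~ Uniform(0, censor_max].  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    network = make_toy_network(spec)

    planted_subsystems = [m.subsystem for m in spec.planted]
    planted_genes: dict[str, str] = {}  # gene -> subsystem
    for rxn in network.reactions:
        if rxn.subsystem in planted_subsystems:
            for g in rxn.genes():
                planted_genes[g] = rxn.subsystem

    samples = [f"S{k:04d}" for k in range(1, spec.n_samples + 1)]
    genes = list(network.genes)
    mu = pd.Series(rng.normal(3.0, 1.0, size=len(genes)), index=genes)
    # keep the planted dynamic range above the null pathways: the biomass
    # bottleneck then stays pinned on a near-constant null chain, so the
    # shared objective does not couple the planted chains to each other
    for g in genes:
        if g in planted_genes:
            mu[g] = max(mu[g], 3.0)
        elif g != "g_atp":
            mu[g] = min(mu[g], 1.0)

    z = pd.DataFrame(
        rng.standard_normal((len(planted_subsystems), spec.n_samples)),
        index=planted_subsystems,
        columns=samples,
    )
    log_fpkm = pd.DataFrame(
        rng.normal(0.0, spec.noise_sd, size=(len(genes), spec.n_samples)),
        index=genes,
        columns=samples,
    )
    log_fpkm = log_fpkm.add(mu, axis=0)
    for g, subsystem in planted_genes.items():
        log_fpkm.loc[g] += spec.loading * z.loc[subsystem]
    expression = np.exp(log_fpkm)

    kinetics = pd.DataFrame(
        {
            "kcat_f": 1.0,
            "kcat_b": 1.0,
            "source": "default",
        },
        index=pd.Index([r.id for r in network.reactions if r.gpr], name="reaction_id"),
    )

    log_hazard = np.zeros(spec.n_samples)
    for m in spec.planted:
        log_hazard += m.beta * z.loc[m.subsystem].to_numpy()
    rate = spec.baseline_hazard * np.exp(log_hazard)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(0.0, spec.censor_max, size=spec.n_samples)
    observed = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    observed = np.maximum(observed, 1e-3)  # survival times must be positive
    survival = [
        SurvivalRecord(s, float(observed[k]), int(event[k]))
        for k, s in enumerate(samples)
    ]

    truth_members = {
        subsystem: sorted(r.id for r in network.reactions if r.subsystem == subsystem)
        for subsystem in planted_subsystems
    }

    truth_subtype = _true_subtypes(spec, z, samples)

    return SyntheticCohort(
        network=network,
        kinetics=kinetics,
        expression=expression,
        survival=survival,
        truth_members=truth_members,
        truth_z=z,
        truth_subtype=truth_subtype,
        spec=spec,
    )


def _true_subtypes(spec: SyntheticSpec, z: pd.DataFrame, samples) -> dict[str, str]:
    """Concordant labels implied by the planted latent activities.

    Uses the first protective (beta < 0) and first harmful (beta > 0)
    planted module; good = protective activity above its median and harmful
    activity below its median.  Empty when no such pair is planted.
    """
    protective = next((m for m in spec.planted if m.beta < 0), None)
    harmful = next((m for m in spec.planted if m.beta > 0), None)
    if protective is None or harmful is None:
        return {}
    zp = z.loc[protective.subsystem]
    zh = z.loc[harmful.subsystem]
    med_p, med_h = zp.median(), zh.median()
    out = {}
    for s in samples:
        if zp[s] > med_p and zh[s] <= med_h:
            out[s] = "concordant_good"
        elif zp[s] <= med_p and zh[s] > med_h:
            out[s] = "concordant_bad"
        else:
            out[s] = "other"
    return out


def ground_truth(cohort: SyntheticCohort) -> dict:
    """Planted structure as plain tables (membership, z, subtype labels)."""
    return {
        "members": cohort.truth_members,
        "latent_activities": cohort.truth_z.to_dict(orient="index"),
        "subtype": dict(cohort.truth_subtype),
        "betas": {m.subsystem: m.beta for m in cohort.spec.planted},
    }


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write the cohort in the same formats the pipeline consumes.

    Returns a mapping of artifact name to path: model JSON, expression TSV
    (gene_id + one column per sample), kinetics TSV, clinical TSV
    (sample_id, time_months, event, idh1_mutant) and truth JSON.
    """
    import json
    from pathlib import Path

    from .network_io import write_model

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "model": outdir / "model.json",
        "expression": outdir / "expression.tsv",
        "kinetics": outdir / "kinetics.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
    }
    write_model(cohort.network, paths["model"])
    expr = cohort.expression.copy()
    expr.index.name = "gene_id"
    expr.to_csv(paths["expression"], sep="\t", float_format="%.10g")
    cohort.kinetics.to_csv(paths["kinetics"], sep="\t", float_format="%.10g")
    clinical = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in cohort.survival],
            "time_months": [r.time for r in cohort.survival],
            "event": [r.event for r in cohort.survival],
            "idh1_mutant": 0,  # constant flag; mutation simulation is out of scope
        }
    )
    clinical.to_csv(paths["clinical"], sep="\t", index=False, float_format="%.10g")
    with open(paths["truth"], "w") as fh:
        json.dump(ground_truth(cohort), fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
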