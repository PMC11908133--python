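"""Synthetic longitudinal CH cohorts with known ground truth.

Emulates the three sampling designs of the study cohorts — LBC (3 waves
near ages 70/76/82), SardiNIA (5 waves over ~20 years) and WHI
(postmenopausal women, baseline 50-79, visits at years 1/3/6/9 plus a
late-life visit) — with gene-dependent fitness, variable acquisition
ages, clone co-occurrence, binomial sequencing noise at realistic depth,
marker trajectories with participant random intercepts, and
proportional-hazards survival times.  Every draw is reproducible from a
seed, and a truth table records the generating clonal structures,
fitness values and acquisition ages for parameter-recovery studies.

Latent clone dynamics are available in two modes: the deterministic
exponential x(t) = exp(s (t - atma)) used throughout the inference
model, and one realization of a linear birth-death process with birth
rate 1+s and death rate 1 per cell-year, sampled exactly at the visit
ages through its binomial / negative-binomial transition law (identical
in distribution to event-by-event simulation) and optionally conditioned
on non-extinction by the first visit via rejection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .growth import GrowthModelParams, clone_size
from .network import GENE_CATEGORIES

__all__ = [
    "CohortDesign",
    "COHORT_DESIGNS",
    "VariantSpec",
    "CloneSpec",
    "TruthRecord",
    "simulate_clone",
    "sample_birth_death",
    "simulate_participant",
    "simulate_cohort",
    "simulate_markers",
    "simulate_survival",
]


# ---------------------------------------------------------------------------
# cohort designs

@dataclass(frozen=True)
class CohortDesign:
    """Visit schedule and sequencing-depth model of one cohort."""

    name: str
    depth_mean: float
    depth_dispersion: float = 20.0  # negative-binomial size parameter
    all_female: bool = False

    def visit_ages(self, rng: np.random.Generator) -> np.ndarray:
        if self.name == "LBC":
            base = rng.normal(70.0, 0.6)
            offs = np.array([0.0, 6.0, 12.0]) + rng.normal(0.0, 0.3, 3)
        elif self.name == "SardiNIA":
            base = rng.uniform(45.0, 65.0)
            offs = np.array([0.0, 5.0, 10.0, 15.0, 20.0]) + rng.normal(0.0, 0.6, 5)
        elif self.name == "WHI":
            base = rng.uniform(50.0, 79.0)
            late = rng.uniform(14.0, 19.0)
            offs = np.array([0.0, 1.0, 3.0, 6.0, 9.0, late])
        else:
            raise ParameterError(f"unknown cohort template {self.name!r}")
        ages = base + np.sort(offs)
        ages[0] = base
        return ages


COHORT_DESIGNS = {
    "LBC": CohortDesign("LBC", depth_mean=2000.0),
    "SardiNIA": CohortDesign("SardiNIA", depth_mean=1000.0),
    "WHI": CohortDesign("WHI", depth_mean=1500.0, all_female=True),
}


# ---------------------------------------------------------------------------
# clone-level simulation

def _bd_transition(counts, dt, lam, mu, rng):
    """Exact linear birth-death transition over dt for a vector of counts."""
    if dt <= 0:
        return counts.copy()
    if abs(lam - mu) > 1e-12:
        w = math.exp((lam - mu) * dt)
        alpha = mu * (w - 1.0) / (lam * w - mu)
        beta = lam * (w - 1.0) / (lam * w - mu)
    else:
        alpha = beta = lam * dt / (1.0 + lam * dt)
    survivors = rng.binomial(counts, 1.0 - alpha)
    out = np.zeros_like(counts)
    pos = survivors > 0
    if np.any(pos):
        out[pos] = survivors[pos] + rng.negative_binomial(survivors[pos], 1.0 - beta)
    return out


def extinction_probability(s: float, dt: float) -> float:
    """P(extinct by dt) for a single founder cell, rates (1+s, 1)."""
    lam, mu = 1.0 + s, 1.0
    if dt <= 0:
        return 0.0
    if s > 1e-12:
        w = math.exp(s * dt)
        return mu * (w - 1.0) / (lam * w - mu)
    return lam * dt / (1.0 + lam * dt)


def sample_birth_death(
    s: float,
    atma: float,
    sample_ages,
    rng: np.random.Generator,
    n: int = 1,
    condition_on_survival: bool = True,
    max_rejection_rounds: int = 1000,
) -> np.ndarray:
    """``n`` birth-death realizations evaluated at ``sample_ages``.

    Birth rate 1+s, death rate 1 per cell-year, one founder cell at
    ``atma``; ages before acquisition report size 0.  With conditioning,
    paths extinct by the first sample age at or after ``atma`` are
    rejection-resampled (clones observed in data necessarily survived).
    """
    if s < 0:
        raise ParameterError(f"fitness must be non-negative, got {s}")
    ages = np.asarray(sample_ages, dtype=float)
    if ages.size == 0:
        return np.zeros((n, 0), dtype=np.int64)
    if np.any(np.diff(ages) < 0):
        raise ParameterError("sample_ages must be sorted")
    lam, mu = 1.0 + s, 1.0
    out = np.zeros((n, ages.size), dtype=np.int64)
    live = ages >= atma
    if not np.any(live):
        return out
    live_ages = ages[live]
    first = live_ages[0]

    def _paths(m):
        counts = np.ones(m, dtype=np.int64)
        path = np.empty((m, live_ages.size), dtype=np.int64)
        prev = atma
        for j, t in enumerate(live_ages):
            counts = _bd_transition(counts, t - prev, lam, mu, rng)
            path[:, j] = counts
            prev = t
        return path

    paths = _paths(n)
    if condition_on_survival:
        for _ in range(max_rejection_rounds):
            dead = paths[:, 0] == 0
            m = int(dead.sum())
            if m == 0:
                break
            paths[dead] = _paths(m)
        else:
            raise RuntimeError(
                f"rejection sampling failed to produce survivors by age {first}"
            )
    out[:, live] = paths
    return out


def simulate_clone(
    s: float,
    atma: float,
    sample_ages,
    params: GrowthModelParams | None = None,
    mode: str = "deterministic",
    seed: int | np.random.Generator = 0,
    condition_on_survival: bool = True,
) -> np.ndarray:
    """Latent clone sizes (cells) at the sample ages.

    ``deterministic`` mode returns exp(s * (t - atma)) (zero before
    acquisition); ``birth_death`` returns one realization of the linear
    birth-death process.
    """
    params = params or GrowthModelParams()
    if s < 0:
        raise ParameterError(f"fitness must be non-negative, got {s}")
    ages = np.asarray(sample_ages, dtype=float)
    if ages.size == 0:
        return np.zeros(0)
    if mode == "deterministic":
        return np.asarray(clone_size(s, atma, ages))
    if mode == "birth_death":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return sample_birth_death(s, atma, ages, rng, n=1, condition_on_survival=condition_on_survival)[0]
    raise ParameterError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# participant-level forward model

@dataclass(frozen=True)
class VariantSpec:
    gene: str
    variant: str
    atma: float

    @property
    def label(self) -> str:
        return f"{self.gene}:{self.variant}"


@dataclass(frozen=True)
class CloneSpec:
    """One clone: a shared fitness and its member variants."""

    s: float
    variants: tuple


@dataclass
class TruthRecord:
    """Generating parameters of one participant."""

    participant_id: str
    blocks: tuple  # tuple of tuples of labels
    fitness: dict  # label -> s
    atma: dict  # label -> years
    log_hazard: float = 0.0
    marker_effects: dict = field(default_factory=dict)


def _latent_vafs(scenario, ages, params):
    """Context-aware model VAFs for every variant at the visit ages."""
    leads = []
    for clone in scenario:
        lead_atma = min(v.atma for v in clone.variants)
        leads.append((clone.s, lead_atma))
    total_lead = np.sum([clone_size(s, a, ages) for s, a in leads], axis=0)
    denom = params.diploid_factor * (params.n_wildtype + total_lead)
    vafs = {}
    for clone in scenario:
        for v in clone.variants:
            vafs[v.label] = np.asarray(clone_size(clone.s, v.atma, ages)) / denom
    return vafs


def simulate_participant(
    scenario,
    visit_ages,
    rng: np.random.Generator,
    participant_id: str = "P0",
    cohort: str = "synthetic",
    sex: str = "F",
    depth_mean: float = 2000.0,
    depth_dispersion: float = 20.0,
    params: GrowthModelParams | None = None,
    gnomad_p: float = 0.001,
):
    """Observed read counts for one participant plus the truth record.

    Observed alt reads are Binomial(depth, VAF_model(t)) with the
    context-aware VAF model; depth is negative-binomial around the
    design mean.  Returns ``(rows, truth)`` where ``rows`` is a list of
    table-row dicts in the cohort_io schema.
    """
    params = params or GrowthModelParams()
    ages = np.asarray(visit_ages, dtype=float)
    scenario = list(scenario)
    labels = [v.label for c in scenario for v in c.variants]
    if len(set(labels)) != len(labels):
        raise ParameterError("clone variants must have distinct labels")
    vafs = _latent_vafs(scenario, ages, params) if scenario else {}

    rows = []
    for clone in scenario:
        for v in clone.variants:
            p = np.clip(vafs[v.label], 0.0, 1.0)
            r = depth_dispersion
            depths = rng.negative_binomial(r, r / (r + depth_mean), size=ages.size) + 1
            alts = rng.binomial(depths, p)
            uaos = rng.binomial(alts, 0.7)
            for t, dpt, ao, uao in zip(ages, depths, alts, uaos):
                rows.append(
                    {
                        "participant_id": participant_id,
                        "cohort": cohort,
                        "gene": v.gene,
                        "variant": v.variant,
                        "age": float(t),
                        "alt_reads": int(ao),
                        "unique_alt_reads": int(uao),
                        "depth": int(dpt),
                        "vaf": float(ao / dpt),
                        "gnomad_p": gnomad_p,
                    }
                )
    truth = TruthRecord(
        participant_id=participant_id,
        blocks=tuple(tuple(v.label for v in c.variants) for c in scenario),
        fitness={v.label: c.s for c in scenario for v in c.variants},
        atma={v.label: v.atma for c in scenario for v in c.variants},
    )
    return rows, truth


# ---------------------------------------------------------------------------
# cohort-level simulation

#: mean fitness per functional category (per year); ordering follows the
#: observed category ranking (splicing high, epigenetic regulation low)
DEFAULT_CATEGORY_FITNESS = {"RS": 0.25, "CS": 0.14, "TF": 0.12, "ST": 0.10, "ER": 0.07}
#: log-scale spread of the per-gene fitness draw
DEFAULT_FITNESS_SIGMA = 0.35

#: sampling weights of mutated genes (DNMT3A/TET2 dominate CH)
_GENE_WEIGHTS = {"DNMT3A": 20.0, "TET2": 10.0, "ASXL1": 4.0, "JAK2": 3.0, "SF3B1": 2.0}


def _draw_gene(rng):
    genes = sorted(GENE_CATEGORIES)
    w = np.array([_GENE_WEIGHTS.get(g, 1.0) for g in genes])
    return genes[rng.choice(len(genes), p=w / w.sum())]


def _draw_fitness(gene, rng, profile=None, sigma=DEFAULT_FITNESS_SIGMA):
    profile = profile or DEFAULT_CATEGORY_FITNESS
    mean = profile.get(GENE_CATEGORIES.get(gene, ""), 0.10)
    return float(np.exp(np.log(mean) + sigma * rng.standard_normal()))


def simulate_cohort(
    template: str,
    n_participants: int,
    gene_fitness_profile: dict | None = None,
    seed: int = 0,
    params: GrowthModelParams | None = None,
    p_n_variants=(0.6, 0.3, 0.1),
    p_cooccur: float = 0.35,
    survival_coefs: dict | None = None,
    marker_effects: dict | None = None,
):
    """A full synthetic cohort in the exact table schemas cohort_io reads.

    Returns a dict with ``variants``, ``covariates`` (including survival),
    ``markers`` and ``truth`` DataFrames.
    """
    if template not in COHORT_DESIGNS:
        raise ParameterError(f"unknown template {template!r}")
    if n_participants < 1:
        raise ParameterError("n_participants must be >= 1")
    design = COHORT_DESIGNS[template]
    params = params or GrowthModelParams()
    rng = np.random.default_rng(seed)

    variant_rows, truth_rows, cov_rows = [], [], []
    visit_ages_by_pid = {}
    for i in range(n_participants):
        pid = f"{template}-{i:04d}"
        ages = design.visit_ages(rng)
        sex = "F" if design.all_female else ("F" if rng.random() < 0.5 else "M")
        k = 1 + rng.choice(len(p_n_variants), p=np.asarray(p_n_variants))
        specs = []
        for j in range(k):
            gene = _draw_gene(rng)
            s = _draw_fitness(gene, rng, gene_fitness_profile)
            # cohort participants were enrolled because CH was detected, so
            # acquisition ages are drawn conditional on the clone reaching
            # roughly detectable VAF (~1%) by the last visit; low-fitness
            # clones stay near the threshold, mirroring the detection limit
            x_det = 2 * 0.01 * params.n_wildtype / (1 - 2 * 0.01)
            a_max = ages[-1] - math.log(x_det) / max(s, 1e-3)
            a_max = min(max(a_max, 1.0), ages[0] - 2.0)
            atma = float(rng.uniform(0.0, a_max))
            specs.append((VariantSpec(gene, f"var{j}", atma), s))
        # group into clones: each later variant joins the previous clone
        # with probability p_cooccur, nesting inside it (later acquisition)
        scenario = [CloneSpec(specs[0][1], (specs[0][0],))]
        for v, s in specs[1:]:
            if rng.random() < p_cooccur:
                host = scenario[-1]
                nested = VariantSpec(
                    v.gene, v.variant, max(v.atma, max(x.atma for x in host.variants) + 1.0)
                )
                scenario[-1] = CloneSpec(host.s, host.variants + (nested,))
            else:
                scenario.append(CloneSpec(s, (v,)))
        rows, truth = simulate_participant(
            scenario,
            ages,
            rng,
            participant_id=pid,
            cohort=template,
            sex=sex,
            depth_mean=design.depth_mean,
            depth_dispersion=design.depth_dispersion,
            params=params,
        )
        variant_rows.extend(rows)
        visit_ages_by_pid[pid] = ages
        max_s = max(truth.fitness.values())
        best_log_macs = max(
            truth.fitness[b[0]] * (params.max_age - min(truth.atma[v] for v in b))
            for b in truth.blocks
        )
        cov_rows.append(
            {
                "participant_id": pid,
                "cohort": template,
                "sex": sex,
                "age_first_obs": float(ages[0]),
                "max_fitness_true": max_s,
                "log_macs120_true": best_log_macs,
                "max_vaf_true": float(
                    max(r["vaf"] for r in rows) if rows else 0.0
                ),
            }
        )
        truth_rows.extend(
            {
                "participant_id": pid,
                "variant": lab,
                "block": "|".join(b),
                "s_true": truth.fitness[lab],
                "atma_true": truth.atma[lab],
            }
            for b in truth.blocks
            for lab in b
        )

    covariates = pd.DataFrame(cov_rows)
    surv = simulate_survival(
        covariates.rename(
            columns={
                "max_vaf_true": "max_vaf",
                "max_fitness_true": "max_fitness",
                "log_macs120_true": "log_macs120",
            }
        ),
        coefs=survival_coefs,
        rng=rng,
    )
    covariates["followup_years"] = surv["time"].to_numpy()
    covariates["event"] = surv["event"].to_numpy()

    markers = simulate_markers(
        covariates.rename(
            columns={
                "max_vaf_true": "max_vaf",
                "max_fitness_true": "max_fitness",
                "log_macs120_true": "log_macs120",
            }
        ),
        visit_ages_by_pid,
        effects_by_marker=marker_effects,
        rng=rng,
    )
    return {
        "variants": pd.DataFrame(variant_rows),
        "covariates": covariates.drop(
            columns=["max_fitness_true", "log_macs120_true", "max_vaf_true"]
        ),
        "markers": markers,
        "truth": pd.DataFrame(truth_rows),
    }


# ---------------------------------------------------------------------------
# markers and survival

#: default marker panel; a few carry true effects of the CH metrics
#: (potassium with max fitness; red-cell indices with clone size / VAF)
DEFAULT_MARKER_EFFECTS = {
    "POTASSIUM": {"max_fitness_z": 0.25},
    "RDW": {"macs120_z": 0.20},
    "MCV": {"max_vaf_z": 0.30, "age:max_vaf_z": -0.03},
    "HGB": {},
    "PLT": {},
    "LYMPH": {},
    "CRP": {},
    "NEUT": {},
}


def _zscore(v):
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=0)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def simulate_markers(
    metrics: pd.DataFrame,
    visit_ages: dict,
    effects_by_marker: dict | None = None,
    random_intercept_sd: float = 0.3,
    residual_sd: float = 1.0,
    rng: np.random.Generator | int = 0,
    binary_markers=(),
) -> pd.DataFrame:
    """Marker trajectories from the association stage's linear mixed model.

    value = b0 + b_age age + b_v maxVAF_z + b_av age*maxVAF_z
          + b_f maxFitness_z + b_m MACS120_z + u_participant + eps,

    with metrics z-scored over the supplied cohort.  Binary markers are
    thresholded at the median of the linear predictor.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    effects_by_marker = (
        DEFAULT_MARKER_EFFECTS if effects_by_marker is None else effects_by_marker
    )
    for pid, ages in visit_ages.items():
        if len(np.atleast_1d(ages)) == 0:
            raise ParameterError(f"participant {pid} has zero visits")

    df = metrics.copy()
    df["max_vaf_z"] = _zscore(df["max_vaf"])
    df["max_fitness_z"] = _zscore(df["max_fitness"])
    df["macs120_z"] = _zscore(df["log_macs120"])

    rows = []
    for marker, eff in effects_by_marker.items():
        u = dict(
            zip(df["participant_id"], random_intercept_sd * rng.standard_normal(len(df)))
        )
        linear = []
        for r in df.itertuples(index=False):
            for age in np.atleast_1d(visit_ages[r.participant_id]):
                mu = (
                    eff.get("intercept", 0.0)
                    + eff.get("age", 0.0) * age
                    + eff.get("max_vaf_z", 0.0) * r.max_vaf_z
                    + eff.get("age:max_vaf_z", 0.0) * age * r.max_vaf_z
                    + eff.get("max_fitness_z", 0.0) * r.max_fitness_z
                    + eff.get("macs120_z", 0.0) * r.macs120_z
                    + u[r.participant_id]
                )
                linear.append((r.participant_id, getattr(r, "cohort", "synthetic"), age, mu))
        values = np.array([m for *_, m in linear]) + residual_sd * rng.standard_normal(
            len(linear)
        )
        if marker in binary_markers:
            values = (values > np.median(values)).astype(float)
        rows.extend(
            {
                "participant_id": pid,
                "cohort": cohort,
                "age": float(age),
                "marker_name": marker,
                "value": float(v),
            }
            for (pid, cohort, age, _), v in zip(linear, values)
        )
    return pd.DataFrame(rows)


DEFAULT_SURVIVAL_COEFS = {
    # log proportional hazards per z-unit; a moderate MACS120 effect with
    # age and sex as the dominant predictors, as in CH epidemiology
    "age_first_obs_z": 1.0,
    "sex_male": 0.3,
    "macs120_z": 0.66,
    "max_vaf_z": 0.0,
    "max_fitness_z": 0.0,
}


def simulate_survival(
    metrics: pd.DataFrame,
    coefs: dict | None = None,
    baseline_hazard: float = 0.02,
    censor_rate: float = 0.4,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Proportional-hazards event times with independent censoring.

    Continuous covariates are z-scored over the supplied table before the
    hazard is computed (matching the fitted model's convention).
    Exponential baseline; censoring times are exponential with rate
    chosen so that roughly ``censor_rate`` of records are censored at
    null effects.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if baseline_hazard <= 0:
        raise ParameterError("baseline_hazard must be positive")
    coefs = DEFAULT_SURVIVAL_COEFS if coefs is None else coefs

    df = metrics.copy()
    if "age_first_obs" in df.columns:
        df["age_first_obs_z"] = _zscore(df["age_first_obs"])
    for src, dst in [
        ("max_vaf", "max_vaf_z"),
        ("max_fitness", "max_fitness_z"),
        ("log_macs120", "macs120_z"),
    ]:
        if src in df.columns:
            df[dst] = _zscore(df[src])
    if "sex" in df.columns:
        df["sex_male"] = (df["sex"] == "M").astype(float)

    eta = np.zeros(len(df))
    for name, beta in coefs.items():
        if beta == 0.0 or name not in df.columns:
            continue
        eta += beta * df[name].to_numpy(dtype=float)

    t_event = rng.exponential(1.0 / (baseline_hazard * np.exp(eta)))
    if censor_rate >= 1.0:
        time, event = t_event, np.zeros(len(df), dtype=int)
    elif censor_rate <= 0.0:
        time, event = t_event, np.ones(len(df), dtype=int)
    else:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=len(df))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "participant_id": df["participant_id"].to_numpy(),
            "time": time,
            "event": event,
        }
    )
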