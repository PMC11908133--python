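"""Clonal-structure enumeration and Bayesian fitness inference.

For a participant carrying k mutations, every set partition of the
mutations into clones is a candidate *clonal structure*: mutations in one
clone share a single fitness value and grow together, mutations in
different clones compete for the stem-cell pool.  Each structure is
scored by its marginal likelihood (model evidence) on the observed
longitudinal read counts:

* latent growth is deterministic-exponential from one cell at the
  (profiled) acquisition age of each variant;
* read counts are emitted binomially around the model VAF, with a
  sequencing-error floor;
* fitness is integrated over a uniform grid, acquisition ages are
  profiled on a 1-year grid (the acquisition age is re-estimated
  continuously afterwards, see :mod:`clonedyn.metrics`).

A variant's VAF denominator contains N, the modelled size of its own
clone's lead variant, and the *data-estimated* sizes of the other
clones' leads: given the observed VAFs v_i of the candidate leads at an
age, the latent sizes follow in closed form from the joint inversion
S = 2VN/(1-2V), x_i = v_i * 2(N + S) with V = sum v_i.  Treating
competitor sizes as data rather than parameters keeps the evidence
factorized over clones (structure search stays tractable for any clone
count) while still explaining the flat or declining VAF trajectories
that subordinate clones show next to a saturating competitor.
:func:`structure_loglik` evaluates the fully parametric cross-clone
likelihood for a given parameter assignment and is available for
diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import ParameterError
from .growth import GrowthModelParams
from .io import ParticipantData, Trajectory

__all__ = [
    "FitnessPosterior",
    "ClonalStructureModel",
    "CloneResult",
    "CloneEstimate",
    "fitness_grid",
    "binom_logpmf",
    "enumerate_structures",
    "structure_loglik",
    "fit_structure",
    "select_structure",
]


def fitness_grid(s_max: float = 1.0, step: float = 0.005) -> np.ndarray:
    """Uniform fitness grid on [0, s_max] (default 201 points)."""
    n = int(round(s_max / step)) + 1
    return np.linspace(0.0, s_max, n)


def binom_logpmf(k, n, p):
    """Binomial log-pmf via log-gamma; accepts real-valued counts.

    Matches ``scipy.stats.binom.logpmf`` on integer counts; real-valued
    counts make noiseless (expected-count) trajectories scorable.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )


# ---------------------------------------------------------------------------
# structure enumeration


def enumerate_structures(variants, max_exhaustive: int = 8):
    """All set partitions of ``variants`` in restricted-growth-string order.

    For ``k <= max_exhaustive`` the full Bell-number set is returned.
    Beyond that a reduced candidate family (single block, all singletons,
    and every pairwise merge of singletons) is returned and flagged via
    the second element of the result tuple ``(partitions, exhaustive)``.
    """
    variants = list(variants)
    if len(set(variants)) != len(variants):
        raise ParameterError("variant labels must be distinct")
    k = len(variants)
    if k == 0:
        return [], True
    if k <= max_exhaustive:
        return _rgs_partitions(variants), True
    singles = tuple((v,) for v in variants)
    reduced = [tuple([tuple(variants)])]
    for i in range(k):
        for j in range(i + 1, k):
            merged = [(variants[i], variants[j])]
            merged += [(v,) for m, v in enumerate(variants) if m not in (i, j)]
            reduced.append(tuple(merged))
    reduced.append(singles)
    return reduced, False


def _rgs_partitions(labels):
    k = len(labels)
    out = []

    def rec(i, rgs, mx):
        if i == k:
            blocks = [[] for _ in range(mx + 1)]
            for lab, a in zip(labels, rgs):
                blocks[a].append(lab)
            out.append(tuple(tuple(b) for b in blocks))
            return
        for j in range(mx + 2):
            rec(i + 1, rgs + [j], max(mx, j))

    if k == 0:
        return []
    rec(1, [0], 0)
    return out


# ---------------------------------------------------------------------------
# data containers


@dataclass
class FitnessPosterior:
    """Posterior over the fitness grid for one clone."""

    grid: np.ndarray
    mass: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.grid.ndim != 1 or np.any(np.diff(self.grid) <= 0):
            raise ParameterError("grid must be strictly increasing 1-D")
        total = self.mass.sum()
        if not math.isfinite(total) or abs(total - 1.0) > 1e-9:
            raise ParameterError("posterior mass must sum to 1")

    @property
    def map_s(self) -> float:
        return float(self.grid[int(np.argmax(self.mass))])

    def quantile(self, q: float) -> float:
        cdf = np.cumsum(self.mass)
        return float(np.interp(q, cdf, self.grid))

    @property
    def iqr(self) -> float:
        return self.quantile(0.75) - self.quantile(0.25)


@dataclass
class ClonalStructureModel:
    """A partition of a participant's variants plus its model evidence."""

    blocks: tuple
    log_evidence: float
    exhaustive: bool = True

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass
class CloneResult:
    """Per-clone estimate: members, lead variant, fitness posterior."""

    variants: tuple
    lead: str
    posterior: FitnessPosterior
    map_s: float
    atma: dict = field(default_factory=dict)  # label -> years or None
    flags: list = field(default_factory=list)


@dataclass
class CloneEstimate:
    """Winning structure with per-clone fitness and per-variant timing."""

    participant_id: str
    structure: ClonalStructureModel
    clones: list
    candidates: list = field(default_factory=list)  # all scored structures
    warnings: list = field(default_factory=list)

    @property
    def max_map_s(self) -> float:
        return max((c.map_s for c in self.clones), default=0.0)

    def atma_of(self, label: str):
        for c in self.clones:
            if label in c.atma:
                return c.atma[label]
        return None

    def clone_of(self, label: str) -> CloneResult:
        for c in self.clones:
            if label in c.variants:
                return c
        raise KeyError(label)


# ---------------------------------------------------------------------------
# likelihoods


def _lead_label(trajs: dict) -> str:
    """Lead variant of a block: highest mean observed VAF, ties by label."""
    return min(trajs, key=lambda lab: (-float(np.mean(trajs[lab].vafs)), lab))


def estimate_lead_sizes(lead_trajs: list, ages, params: GrowthModelParams):
    """Data-estimated latent sizes of competing lead variants at ``ages``.

    Observed lead VAFs are linearly interpolated in age (clamped at the
    ends), then jointly inverted:  with V the summed lead VAFs, the total
    mutant mass is S = 2VN/(1-2V) and each lead's size is
    x_i = v_i * diploid_factor * (N + S).  Returns an array of shape
    ``(n_leads, n_ages)``.
    """
    ages = np.asarray(ages, dtype=float)
    if not lead_trajs:
        return np.zeros((0, ages.size))
    df, N = params.diploid_factor, params.n_wildtype
    vafs = np.vstack([np.interp(ages, t.ages, t.vafs) for t in lead_trajs])
    dfv = np.clip(df * vafs.sum(axis=0), 0.0, 0.98)  # df*V < 1 for invertibility
    s_total = dfv * N / (1.0 - dfv)
    return vafs * df * (N + s_total)


def structure_loglik(
    trajectories,
    partition,
    s_per_clone,
    atma_per_variant: dict,
    params: GrowthModelParams | None = None,
) -> float:
    """Full context-aware log-likelihood at an explicit parameter assignment.

    Every variant's VAF denominator contains N plus the summed sizes of
    *all* clones' lead variants.  Observations before a variant's
    acquisition are scored at the sequencing-error floor; depth-0
    observations are skipped.
    """
    params = params or GrowthModelParams()
    trajs = {t.label: t for t in trajectories}
    if not trajs:
        return 0.0
    blocks = [tuple(b) for b in partition]
    assigned = [lab for b in blocks for lab in b]
    if sorted(assigned) != sorted(trajs):
        raise ParameterError("partition must cover every variant exactly once")
    s_per_clone = np.asarray(s_per_clone, dtype=float)
    if np.any(s_per_clone < 0):
        raise ParameterError("fitness values must be non-negative")

    all_ages = np.unique(np.concatenate([trajs[lab].ages for lab in assigned]))
    # summed lead sizes at every observation age
    lead_total = np.zeros_like(all_ages)
    for b, s in zip(blocks, s_per_clone):
        lead = _lead_label({lab: trajs[lab] for lab in b})
        a = atma_per_variant[lead]
        dt = all_ages - a
        lead_total += np.where(dt >= 0, np.exp(s * dt), 0.0)

    denom = params.diploid_factor * (params.n_wildtype + lead_total)
    age_index = {age: i for i, age in enumerate(all_ages)}

    total = 0.0
    for b, s in zip(blocks, s_per_clone):
        for lab in b:
            t = trajs[lab]
            a = atma_per_variant[lab]
            for o in t.observations:
                if o.depth == 0:
                    import warnings as _w

                    _w.warn(f"depth 0 at {lab} age {o.age}; skipped", stacklevel=2)
                    continue
                dt = o.age - a
                x = math.exp(s * dt) if dt >= 0 else 0.0
                p = x / denom[age_index[o.age]] if x > 0 else params.error_floor
                total += float(binom_logpmf(o.alt_reads, o.depth, p))
    return total


def _profile_block(
    trajs: dict,
    grid: np.ndarray,
    params: GrowthModelParams,
    competitors: dict | None = None,
):
    """Profiled log-likelihood of one clone over the fitness grid.

    Acquisition ages are profiled on a 1-year grid: the lead variant
    first, then every other member with the lead size fixed and its
    acquisition constrained to be no earlier than the lead's.  Each
    member's VAF denominator is ``N + x_lead(model) + S_other(data)``
    where ``competitors`` maps each member label to the data-estimated
    summed sizes of the other clones' leads at that member's observation
    ages (zero when the clone is alone).

    Returns ``(loglik (G,), atma_hat: {label: (G,) years}, lead_label)``.
    """
    G = len(grid)
    df, N, floor = params.diploid_factor, params.n_wildtype, params.error_floor
    lead = _lead_label(trajs)
    competitors = competitors or {}

    def _grid_ll(t: Trajectory, lead_size=None, min_age=None):
        ages, ao, d = t.ages, t.alt_reads, t.depths
        s_other = competitors.get(t.label)
        s_other = np.zeros_like(ages) if s_other is None else np.asarray(s_other)
        agrid = np.arange(0.0, math.floor(ages[0]) + 1.0)
        dt = ages[None, None, :] - agrid[None, :, None]  # (1, A, n)
        x = np.where(dt >= 0, np.exp(grid[:, None, None] * dt), 0.0)  # (G, A, n)
        if lead_size is None:
            denom = df * (N + x + s_other[None, None, :])
        else:
            denom = df * (N + lead_size[:, None, :] + s_other[None, None, :])
        # pre-acquisition observations are scored at the error floor; combos
        # with acquisition before the lead's can exceed VAF 1 but are masked
        # below, so clip them out of the log's domain
        p = np.where(x > 0, np.minimum(x / denom, 1.0 - floor), floor)
        ll = binom_logpmf(ao[None, None, :], d[None, None, :], p).sum(axis=2)  # (G, A)
        if min_age is not None:
            mask = agrid[None, :] < min_age[:, None]
            ok = ~np.all(mask, axis=1)
            ll = np.where(mask & ok[:, None], -np.inf, ll)
        j = np.argmax(ll, axis=1)
        rows = np.arange(G)
        return ll[rows, j], agrid[j]

    ll_lead, a_lead = _grid_ll(trajs[lead])
    total = ll_lead.copy()
    atma_hat = {lead: a_lead}
    for lab in sorted(trajs):
        if lab == lead:
            continue
        t = trajs[lab]
        dt_lead = t.ages[None, :] - a_lead[:, None]  # (G, n)
        x_lead = np.where(dt_lead >= 0, np.exp(grid[:, None] * dt_lead), 0.0)
        ll_v, a_v = _grid_ll(t, lead_size=x_lead, min_age=a_lead)
        total += ll_v
        atma_hat[lab] = a_v
    return total, atma_hat, lead


def fit_structure(
    trajectories,
    partition,
    params: GrowthModelParams | None = None,
    grid: np.ndarray | None = None,
    _block_cache: dict | None = None,
):
    """Score one candidate partition.

    Returns ``(posteriors, log_evidence, details)`` where ``posteriors``
    is one :class:`FitnessPosterior` per block (uniform prior on the
    grid, acquisition ages profiled) and ``details`` carries per-block
    lead labels and grid-profiled acquisition ages at the MAP fitness.
    The evidence is the product over blocks of the grid-averaged
    marginal likelihood.
    """
    params = params or GrowthModelParams()
    grid = fitness_grid() if grid is None else np.asarray(grid, dtype=float)
    trajs = {t.label: t for t in trajectories}
    cache = _block_cache if _block_cache is not None else {}

    block_leads = {
        frozenset(b): _lead_label({lab: trajs[lab] for lab in b}) for b in partition
    }
    posteriors, details = [], []
    log_evidence = 0.0
    for block in partition:
        other_leads = sorted(
            lead for b, lead in block_leads.items() if b != frozenset(block)
        )
        key = (frozenset(block), tuple(other_leads))
        if key not in cache:
            # invert jointly over every lead (own included) for consistent
            # sizes, then keep only the competitors' contribution
            own_lead = block_leads[frozenset(block)]
            all_leads = sorted(set(other_leads) | {own_lead})
            lead_trajs = [trajs[lab] for lab in all_leads]
            keep = [i for i, lab in enumerate(all_leads) if lab != own_lead]
            competitors = {
                lab: estimate_lead_sizes(lead_trajs, trajs[lab].ages, params)[keep].sum(axis=0)
                for lab in block
            }
            cache[key] = _profile_block(
                {lab: trajs[lab] for lab in block}, grid, params, competitors
            )
        ll, atma_hat, lead = cache[key]
        log_ev_block = float(logsumexp(ll) - math.log(len(grid)))
        with np.errstate(under="ignore"):
            mass = np.exp(ll - logsumexp(ll))
        mass /= mass.sum()
        post = FitnessPosterior(grid=grid, mass=mass)
        g_map = int(np.argmax(mass))
        posteriors.append(post)
        details.append(
            {
                "lead": lead,
                "atma_grid": {lab: float(a[g_map]) for lab, a in atma_hat.items()},
            }
        )
        log_evidence += log_ev_block
    return posteriors, log_evidence, details


def select_structure(
    participant: ParticipantData,
    params: GrowthModelParams | None = None,
    grid: np.ndarray | None = None,
    max_exhaustive: int = 8,
) -> CloneEstimate:
    """Enumerate, score and select the most probable clonal structure.

    Evidence ties are broken toward more blocks (more independent
    clones), then canonical enumeration order; ties are recorded in the
    estimate's warning list.  Per-variant acquisition ages are the
    grid-profiled values; refine them with
    :func:`clonedyn.metrics.estimate_atma` (or use
    :func:`clonedyn.pipeline.analyze_participant`).
    """
    params = params or GrowthModelParams()
    grid = fitness_grid() if grid is None else np.asarray(grid, dtype=float)
    trajectories = participant.trajectories
    if not trajectories:
        raise ParameterError(f"participant {participant.participant_id} has no trajectories")
    labels = sorted(t.label for t in trajectories)

    cache: dict = {}
    k = len(labels)
    if k <= max_exhaustive:
        partitions, exhaustive = enumerate_structures(labels, max_exhaustive)
        scored = [
            (partition, *fit_structure(trajectories, partition, params, grid, cache))
            for partition in partitions
        ]
    else:
        scored, exhaustive = _greedy_partitions(trajectories, labels, params, grid, cache)

    best_i = max(
        range(len(scored)),
        key=lambda i: (scored[i][2], len(scored[i][0]), -i),
    )
    partition, posteriors, log_ev, details = scored[best_i]

    warnings_list = []
    for i, entry in enumerate(scored):
        if i != best_i and abs(entry[2] - log_ev) < 1e-9:
            warnings_list.append(f"evidence tie with partition {entry[0]}")

    clones = []
    for block, post, det in zip(partition, posteriors, details):
        clones.append(
            CloneResult(
                variants=tuple(block),
                lead=det["lead"],
                posterior=post,
                map_s=post.map_s,
                atma={lab: det["atma_grid"][lab] for lab in block},
            )
        )
    structure = ClonalStructureModel(
        blocks=tuple(tuple(b) for b in partition),
        log_evidence=log_ev,
        exhaustive=exhaustive,
    )
    candidates = [
        ClonalStructureModel(tuple(tuple(b) for b in p), ev, exhaustive)
        for (p, _, ev, _) in scored
    ]
    return CloneEstimate(
        participant_id=participant.participant_id,
        structure=structure,
        clones=clones,
        candidates=candidates,
        warnings=warnings_list,
    )


def _greedy_partitions(trajectories, labels, params, grid, cache):
    """Agglomerative search for large mutation sets (flagged non-exhaustive).

    Seeded from all singletons; repeatedly merges the pair of blocks that
    most increases the evidence until no merge improves.  Returns every
    partition visited, scored.
    """
    current = [(lab,) for lab in labels]
    scored = []

    def score(partition):
        entry = (partition, *fit_structure(trajectories, partition, params, grid, cache))
        scored.append(entry)
        return entry[2]

    best = score(tuple(current))
    improved = True
    while improved and len(current) > 1:
        improved = False
        best_merge = None
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                cand = [b for m, b in enumerate(current) if m not in (i, j)]
                cand.append(tuple(current[i]) + tuple(current[j]))
                cand = sorted(cand)
                ev = score(tuple(cand))
                if ev > best:
                    best, best_merge, improved = ev, cand, True
        if best_merge is not None:
            current = best_merge
    return scored, False
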