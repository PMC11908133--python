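"""Reading, validation, filtering and harmonization of longitudinal tables.

The pipeline consumes long-format variant-call tables (one row per
participant, visit and variant), per-participant covariate/survival
tables, and longitudinal blood-marker tables.  This module turns them
into the in-memory data model (:class:`MutationObservation`,
:class:`Trajectory`, :class:`ParticipantData`) and applies the standard
CH variant filters: minimum VAF, read support (AO/UAO), gnomAD
under-representation, and a germline-stability check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRecordError,
    EmptyInputError,
    RowError,
    SchemaError,
)

__all__ = [
    "MutationObservation",
    "Trajectory",
    "ParticipantData",
    "MarkerSeries",
    "read_variant_table",
    "write_variant_table",
    "read_covariate_table",
    "read_marker_table",
    "apply_variant_filters",
    "build_trajectories",
    "read_curation_list",
]

COHORTS = ("LBC", "SardiNIA", "WHI", "synthetic")

#: canonical column names and their accepted aliases
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "participant_id": ("participant_id", "participant", "sample_id", "id"),
    "cohort": ("cohort", "study"),
    "gene": ("gene", "gene_symbol", "symbol"),
    "variant": ("variant", "protein_change", "aa_change", "mutation"),
    "age": ("age", "age_at_visit", "wave_age"),
    "alt_reads": ("alt_reads", "ao", "alt_count"),
    "unique_alt_reads": ("unique_alt_reads", "uao", "unique_alt_count"),
    "depth": ("depth", "dp", "total_depth", "coverage"),
    "vaf": ("vaf", "af", "allele_frequency"),
    "gnomad_p": ("gnomad_p", "gnomad_pvalue", "gnomad"),
}

_REQUIRED = ("participant_id", "gene", "variant", "age", "depth")
_OPTIONAL = ("cohort", "alt_reads", "unique_alt_reads", "vaf", "gnomad_p")


@dataclass(frozen=True)
class MutationObservation:
    """A single variant call at one visit of one participant."""

    participant_id: str
    cohort: str
    gene: str
    variant: str
    age: float
    alt_reads: int
    depth: int
    vaf: float
    unique_alt_reads: int | None = None
    gnomad_p: float | None = None

    @property
    def label(self) -> str:
        return f"{self.gene}:{self.variant}"

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError("alt_reads must lie in [0, depth]")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("vaf must lie in [0, 1]")
        if abs(self.vaf - self.alt_reads / self.depth) > 0.5 / self.depth + 1e-12:
            raise ValueError("vaf inconsistent with alt_reads/depth")


@dataclass
class Trajectory:
    """Time-ordered VAF observations of one mutation in one participant."""

    participant_id: str
    gene: str
    variant: str
    observations: list[MutationObservation]

    @property
    def label(self) -> str:
        return f"{self.gene}:{self.variant}"

    @property
    def ages(self) -> np.ndarray:
        return np.array([o.age for o in self.observations], dtype=float)

    @property
    def alt_reads(self) -> np.ndarray:
        return np.array([o.alt_reads for o in self.observations], dtype=float)

    @property
    def depths(self) -> np.ndarray:
        return np.array([o.depth for o in self.observations], dtype=float)

    @property
    def vafs(self) -> np.ndarray:
        return np.array([o.vaf for o in self.observations], dtype=float)

    def validate(self) -> None:
        if not self.observations:
            raise ValueError("trajectory needs >= 1 observation")
        ages = self.ages
        if not np.all(np.diff(ages) > 0):
            raise ValueError("observation ages must be strictly increasing")
        for o in self.observations:
            if (o.participant_id, o.gene, o.variant) != (
                self.participant_id,
                self.gene,
                self.variant,
            ):
                raise ValueError("observation does not belong to this trajectory")


@dataclass
class MarkerSeries:
    """Longitudinal measurements of one blood marker for one participant."""

    participant_id: str
    cohort: str
    marker: str
    ages: list[float]
    values: list[float]
    is_binary: bool = False


@dataclass
class ParticipantData:
    """All pipeline inputs for one participant."""

    participant_id: str
    cohort: str
    sex: str | None = None
    trajectories: list[Trajectory] = field(default_factory=list)
    survival: tuple[float, int] | None = None
    markers: list[MarkerSeries] = field(default_factory=list)

    @property
    def age_first_obs(self) -> float | None:
        ages = [o.age for t in self.trajectories for o in t.observations]
        return min(ages) if ages else None


def _resolve_columns(columns) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for canonical, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[canonical] = lower[alias]
                break
    return resolved


def read_variant_table(path, dialect: str = "tsv") -> list[MutationObservation]:
    """Read a long-format variant table into observations.

    VAF is recomputed from ``alt_reads/depth`` whenever both are present;
    otherwise the ``vaf`` column is used as-is.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = _resolve_columns(df.columns)
    missing = [c for c in _REQUIRED if c not in cols]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "alt_reads" not in cols and "vaf" not in cols:
        raise SchemaError("need at least one of: alt_reads, vaf")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")

    out: list[MutationObservation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = {c: row[df.columns.get_loc(cols[c])] for c in cols}
        try:
            depth = int(float(rec["depth"]))
            age = float(rec["age"])
            alt = rec.get("alt_reads")
            alt_reads = int(float(alt)) if _present(alt) else None
            vaf_cell = rec.get("vaf")
            vaf = float(vaf_cell) if _present(vaf_cell) else None
            uao_cell = rec.get("unique_alt_reads")
            uao = int(float(uao_cell)) if _present(uao_cell) else None
            gp_cell = rec.get("gnomad_p")
            gnomad_p = float(gp_cell) if _present(gp_cell) else None
        except (TypeError, ValueError) as exc:
            raise RowError(i, f"unparsable numeric cell ({exc})") from None
        if depth <= 0:
            raise RowError(i, f"depth must be positive, got {depth}")
        if alt_reads is None:
            alt_reads = int(round(vaf * depth))
        else:
            vaf = alt_reads / depth
        if not 0 <= alt_reads <= depth:
            raise RowError(i, f"alt_reads {alt_reads} outside [0, depth={depth}]")
        obs = MutationObservation(
            participant_id=str(rec["participant_id"]),
            cohort=str(rec.get("cohort", "synthetic") or "synthetic"),
            gene=str(rec["gene"]),
            variant=str(rec["variant"]),
            age=age,
            alt_reads=alt_reads,
            depth=depth,
            vaf=vaf,
            unique_alt_reads=uao,
            gnomad_p=gnomad_p,
        )
        obs.validate()
        out.append(obs)
    return out


def _present(cell) -> bool:
    if cell is None:
        return False
    if isinstance(cell, float) and math.isnan(cell):
        return False
    s = str(cell).strip()
    return s not in ("", "NA", "nan", "NaN", ".")


def write_variant_table(obs: list[MutationObservation], path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.DataFrame(
        {
            "participant_id": [o.participant_id for o in obs],
            "cohort": [o.cohort for o in obs],
            "gene": [o.gene for o in obs],
            "variant": [o.variant for o in obs],
            "age": [repr(o.age) for o in obs],
            "alt_reads": [o.alt_reads for o in obs],
            "unique_alt_reads": ["" if o.unique_alt_reads is None else o.unique_alt_reads for o in obs],
            "depth": [o.depth for o in obs],
            "vaf": [repr(o.vaf) for o in obs],
            "gnomad_p": ["" if o.gnomad_p is None else repr(o.gnomad_p) for o in obs],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def read_covariate_table(path) -> pd.DataFrame:
    """Covariate/survival table: participant_id, sex, age_first_obs, followup_years, event."""
    df = pd.read_csv(path, sep="\t")
    required = {"participant_id", "sex", "age_first_obs", "followup_years", "event"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def read_marker_table(path) -> pd.DataFrame:
    """Marker table: participant_id, cohort, age, marker_name, value."""
    df = pd.read_csv(path, sep="\t")
    required = {"participant_id", "cohort", "age", "marker_name", "value"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def read_curation_list(path) -> set[str]:
    """Plain-text curation list, one ``gene:variant`` per line; '#' comments."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    return out


# ---------------------------------------------------------------------------
# variant filters

_RULE_ORDER = ("VAF", "AO", "UAO", "gnomAD")


def _obs_failures(o: MutationObservation, min_vaf, min_ao, min_uao, gnomad_alpha):
    fails = []
    if o.vaf < min_vaf:
        fails.append("VAF")
    if o.alt_reads < min_ao:
        fails.append("AO")
    if o.unique_alt_reads is not None and o.unique_alt_reads < min_uao:
        fails.append("UAO")
    if o.gnomad_p is not None and o.gnomad_p > gnomad_alpha:
        fails.append("gnomAD")
    return fails


def apply_variant_filters(
    obs: list[MutationObservation],
    min_vaf: float = 0.01,
    min_ao: int = 5,
    min_uao: int = 3,
    gnomad_alpha: float = 0.05,
    germline_tol: float = 0.05,
    denylist: set[str] | None = None,
    allowlist: set[str] | None = None,
):
    """Apply the CH variant filters; never raises.

    A variant is kept when *any* of its time points simultaneously passes
    the VAF, AO, UAO and gnomAD rules; once kept, **all** participant-
    matched observations of that variant are kept regardless of baseline
    VAF.  Variants whose VAF sits within ``germline_tol`` of 0.5 (or of
    1.0) at every wave are rejected as germline.  ``denylist`` entries
    (``gene:variant``) are always rejected, ``allowlist`` entries always
    kept (manual curation), unless malformed.

    Returns ``(kept, rejected)`` where ``rejected`` is a list of
    ``(observation, reason)`` pairs with reasons among
    ``malformed, denylist, germline-stable, VAF, AO, UAO, gnomAD``.
    """
    denylist = denylist or set()
    allowlist = allowlist or set()
    kept: list[MutationObservation] = []
    rejected: list[tuple[MutationObservation, str]] = []

    groups: dict[tuple[str, str, str], list[MutationObservation]] = {}
    for o in obs:
        try:
            o.validate()
        except ValueError:
            rejected.append((o, "malformed"))
            continue
        groups.setdefault((o.participant_id, o.gene, o.variant), []).append(o)

    for (_, gene, variant), group in groups.items():
        group = sorted(group, key=lambda o: o.age)
        label = f"{gene}:{variant}"
        if label in denylist:
            rejected.extend((o, "denylist") for o in group)
            continue
        if label in allowlist:
            kept.extend(group)
            continue
        vafs = np.array([o.vaf for o in group])
        if np.all(np.abs(vafs - 0.5) <= germline_tol) or np.all(
            np.abs(vafs - 1.0) <= germline_tol
        ):
            rejected.extend((o, "germline-stable") for o in group)
            continue
        fails = [_obs_failures(o, min_vaf, min_ao, min_uao, gnomad_alpha) for o in group]
        if any(not f for f in fails):
            kept.extend(group)
        else:
            # reason: first failing rule of the observation closest to passing
            # (fewest failures; ties -> highest VAF, then earliest age)
            order = sorted(
                range(len(group)),
                key=lambda i: (len(fails[i]), -group[i].vaf, group[i].age),
            )
            best = fails[order[0]]
            reason = next(r for r in _RULE_ORDER if r in best)
            rejected.extend((o, reason) for o in group)
    return kept, rejected


def build_trajectories(
    obs: list[MutationObservation],
    covariates: pd.DataFrame | None = None,
    markers: pd.DataFrame | None = None,
) -> list[ParticipantData]:
    """Group filtered observations into per-participant trajectories.

    Participants present in ``covariates`` but without surviving variants
    are still emitted (empty trajectory list) so the survival and marker
    stages see them.
    """
    keyed: dict[tuple[str, str, str], list[MutationObservation]] = {}
    dupes = []
    for o in obs:
        key = (o.participant_id, o.gene, o.variant)
        bucket = keyed.setdefault(key, [])
        if any(b.age == o.age for b in bucket):
            dupes.append((*key, o.age))
        bucket.append(o)
    if dupes:
        raise DuplicateRecordError(dupes)

    participants: dict[str, ParticipantData] = {}

    def _participant(pid: str, cohort: str) -> ParticipantData:
        if pid not in participants:
            participants[pid] = ParticipantData(participant_id=pid, cohort=cohort)
        return participants[pid]

    for (pid, gene, variant), group in keyed.items():
        group = sorted(group, key=lambda o: o.age)
        traj = Trajectory(pid, gene, variant, group)
        traj.validate()
        _participant(pid, group[0].cohort).trajectories.append(traj)

    if covariates is not None:
        for row in covariates.itertuples(index=False):
            p = _participant(str(row.participant_id), getattr(row, "cohort", "synthetic"))
            p.sex = str(row.sex)
            p.survival = (float(row.followup_years), int(row.event))

    if markers is not None:
        for (pid, marker), sub in markers.groupby(["participant_id", "marker_name"]):
            pid = str(pid)
            if pid not in participants:
                continue
            sub = sub.sort_values("age")
            values = sub["value"].to_numpy(dtype=float)
            participants[pid].markers.append(
                MarkerSeries(
                    participant_id=pid,
                    cohort=str(sub["cohort"].iloc[0]),
                    marker=str(marker),
                    ages=sub["age"].to_numpy(dtype=float).tolist(),
                    values=values.tolist(),
                    is_binary=len(np.unique(values)) == 2,
                )
            )

    return sorted(participants.values(), key=lambda p: p.participant_id)
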