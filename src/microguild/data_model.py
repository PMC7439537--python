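"""Study design constants, domain tables, readers, and table-level filters.

All tabular I/O is plain TSV (UTF-8, tab-delimited, ``.`` decimal).
Abundance tables are canonicalised to samples x OTUs orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TIMEPOINTS = ("BL", "W1", "W6")
ARMS = ("AX", "MCC")

SCFA_COLUMNS = ("acetate", "propionate", "butyrate", "isobutyrate", "isovalerate")


class FormatError(ValueError):
    """A table on disk violates the expected format or an invariant."""


@dataclass(frozen=True)
class StudyDesign:
    """Two-arm fiber trial design: full daily dose by sex, half dose on run-in days.

    Females receive 25 g/day, males 35 g/day; the first ``half_dose_days``
    days of treatment use exactly half the full dose.
    """

    arms: tuple[str, ...] = ARMS
    dose_by_sex: dict[str, float] = field(
        default_factory=lambda: {"female": 25.0, "male": 35.0}
    )
    half_dose_days: int = 2
    timepoints: tuple[str, ...] = TIMEPOINTS

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(set(self.timepoints)):
            raise ValueError("timepoints must be strictly ordered and unique")
        if self.half_dose_days < 0:
            raise ValueError("half_dose_days must be non-negative")
        for sex, dose in self.dose_by_sex.items():
            if dose <= 0:
                raise ValueError(f"dose for {sex!r} must be positive")

    def full_dose(self, sex: str) -> float:
        return self.dose_by_sex[sex]

    def half_dose(self, sex: str) -> float:
        """Run-in daily dose: exactly half the full dose."""
        return self.dose_by_sex[sex] / 2.0


def monosaccharide_weight_ratio(numerator_pct: float, denominator_pct: float) -> float:
    """Weight ratio of two monosaccharide percentages (e.g. arabinose:xylose).

    Indexes branching density of an arabinoxylan: the backbone sugar goes in
    the denominator, the side-chain sugar in the numerator.
    """
    if numerator_pct < 0 or denominator_pct <= 0:
        raise ValueError("percentages must be non-negative with a positive denominator")
    return numerator_pct / denominator_pct


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample link to subject, arm, sex, dose, and timepoint."""

    sample_id: str
    subject_id: str
    arm: str
    sex: str
    dose: float
    timepoint: str


class MetadataTable:
    """Collection of :class:`SampleMetadata` keyed by sample id.

    Enforces that each (subject, timepoint) pair appears at most once and
    that dose is consistent with sex under the given design.
    """

    def __init__(
        self, records: list[SampleMetadata], design: StudyDesign | None = None
    ) -> None:
        seen: set[tuple[str, str]] = set()
        by_sample: dict[str, SampleMetadata] = {}
        for rec in records:
            key = (rec.subject_id, rec.timepoint)
            if key in seen:
                raise FormatError(
                    f"duplicate (subject, timepoint) pair {key} in metadata"
                )
            seen.add(key)
            if rec.sample_id in by_sample:
                raise FormatError(f"duplicate sample id {rec.sample_id!r}")
            if design is not None:
                expected = design.full_dose(rec.sex)
                if abs(rec.dose - expected) > 1e-9:
                    raise FormatError(
                        f"sample {rec.sample_id!r}: dose {rec.dose} inconsistent "
                        f"with sex {rec.sex!r} (expected {expected})"
                    )
            by_sample[rec.sample_id] = rec
        self._by_sample = by_sample

    def __getitem__(self, sample_id: str) -> SampleMetadata:
        return self._by_sample[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_sample

    def __iter__(self):
        return iter(self._by_sample.values())

    def __len__(self) -> int:
        return len(self._by_sample)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._by_sample)

    def subjects(self) -> list[str]:
        out: list[str] = []
        for rec in self:
            if rec.subject_id not in out:
                out.append(rec.subject_id)
        return out

    def sample_for(self, subject_id: str, timepoint: str) -> str | None:
        for rec in self:
            if rec.subject_id == subject_id and rec.timepoint == timepoint:
                return rec.sample_id
        return None

    def arm_of(self, subject_id: str) -> str:
        for rec in self:
            if rec.subject_id == subject_id:
                return rec.arm
        raise KeyError(subject_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "subject_id": r.subject_id,
                    "arm": r.arm,
                    "sex": r.sex,
                    "dose": r.dose,
                    "timepoint": r.timepoint,
                }
                for r in self
            ]
        ).set_index("sample_id")

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, design: StudyDesign | None = None
    ) -> "MetadataTable":
        frame = frame.reset_index() if frame.index.name == "sample_id" else frame
        records = [
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                subject_id=str(row["subject_id"]),
                arm=str(row["arm"]),
                sex=str(row["sex"]),
                dose=float(row["dose"]),
                timepoint=str(row["timepoint"]),
            )
            for _, row in frame.iterrows()
        ]
        return cls(records, design=design)


def read_metadata_table(path, design: StudyDesign | None = None) -> MetadataTable:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subject_id", "arm", "sex", "dose", "timepoint"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    frame["dose"] = frame["dose"].astype(float)
    return MetadataTable.from_frame(frame, design=design)


def write_metadata_table(meta: MetadataTable, path) -> None:
    meta.to_frame().to_csv(path, sep="\t")


class AbundanceTable:
    """Samples x OTUs table of counts or relative abundances.

    Counts must be non-negative; relative rows must sum to at most one
    (exactly one for a closed composition — subsetting OTUs deliberately
    leaves a subcomposition that is NOT re-closed).
    """

    def __init__(
        self,
        sample_ids: list[str],
        otu_ids: list[str],
        values: np.ndarray,
        mode: str,
        taxonomy: dict[str, str] | None = None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(sample_ids), len(otu_ids)):
            raise FormatError(
                f"value shape {values.shape} does not match "
                f"{len(sample_ids)} samples x {len(otu_ids)} OTUs"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(otu_ids)) != len(otu_ids):
            raise FormatError("duplicate OTU ids")
        if np.any(values < 0):
            raise FormatError("negative abundance values")
        if mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "relative":
            sums = values.sum(axis=1)
            bad = np.flatnonzero(sums > 1.0 + 1e-9)
            if bad.size:
                raise FormatError(
                    f"relative rows must sum to at most 1 "
                    f"(first violation: {sample_ids[bad[0]]!r})"
                )
        self.sample_ids = list(sample_ids)
        self.otu_ids = list(otu_ids)
        self.values = values
        self.mode = mode
        self.taxonomy = dict(taxonomy) if taxonomy else None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def select_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceTable(
            sample_ids, self.otu_ids, self.values[idx], self.mode, self.taxonomy
        )

    def select_otus(self, otu_ids: list[str]) -> "AbundanceTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        tax = (
            {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
            if self.taxonomy
            else None
        )
        return AbundanceTable(self.sample_ids, otu_ids, self.values[:, idx], self.mode, tax)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)


def read_abundance_table(path, mode: str, transposed: bool = False) -> AbundanceTable:
    """Read a TSV abundance table (first column sample ids, header OTU ids).

    With ``transposed=True`` the file is OTUs x samples and is flipped to the
    canonical samples x OTUs orientation.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if transposed:
        frame = frame.T
    values = frame.to_numpy(dtype=float)
    if np.any(np.isnan(values)):
        raise FormatError("abundance table contains missing values")
    if mode == "counts" and np.any(np.abs(values - np.round(values)) > 1e-9):
        raise FormatError("counts mode requires integer values")
    if mode == "relative" and np.any(values.sum(axis=1) > 1.0 + 1e-6):
        raise FormatError("relative table rows must sum to at most 1")
    return AbundanceTable(
        [str(s) for s in frame.index], [str(o) for o in frame.columns], values, mode
    )


def read_biom_json(path) -> AbundanceTable:
    """Read a BIOM-format 1.0 JSON count table (sparse or dense).

    BIOM stores observations (OTUs) as rows and samples as columns; the
    result is transposed to the canonical samples x OTUs orientation.
    """
    import json

    payload = json.loads(Path(path).read_text())
    otu_ids = [str(r["id"]) for r in payload["rows"]]
    sample_ids = [str(c["id"]) for c in payload["columns"]]
    dense = np.zeros((len(otu_ids), len(sample_ids)))
    if payload.get("matrix_type") == "dense":
        dense = np.asarray(payload["data"], dtype=float)
    else:
        for i, j, v in payload["data"]:
            dense[int(i), int(j)] = v
    taxonomy = {
        str(r["id"]): "; ".join(r["metadata"]["taxonomy"])
        for r in payload["rows"]
        if isinstance(r.get("metadata"), dict) and "taxonomy" in r["metadata"]
    }
    return AbundanceTable(sample_ids, otu_ids, dense.T, "counts", taxonomy or None)


def write_abundance_table(table: AbundanceTable, path) -> None:
    frame = table.to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Close each sample's counts to relative abundances summing to one."""
    if table.mode != "counts":
        raise ValueError("input must be in counts mode")
    sums = table.values.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"sample {table.sample_ids[zero[0]]!r} has zero total count")
    return AbundanceTable(
        table.sample_ids,
        table.otu_ids,
        table.values / sums[:, None],
        "relative",
        table.taxonomy,
    )


def filter_low_abundance(
    table: AbundanceTable, threshold: float = 0.0015
) -> AbundanceTable:
    """Keep OTUs whose mean relative abundance over all samples >= threshold.

    The mean is taken over every sample in the table (all arms and all
    timepoints pooled). Rows are NOT re-closed afterwards; downstream
    operations decide whether to renormalise.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if table.mode == "counts":
        rel = to_relative_abundance(table).values
    else:
        rel = table.values
    means = rel.mean(axis=0)
    keep = [o for o, m in zip(table.otu_ids, means) if m >= threshold]
    if not keep:
        raise ValueError("threshold removes every OTU")
    return table.select_otus(keep)


def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample each sample without replacement to ``depth`` reads.

    Samples with total count <= depth are left unchanged. Subsampling is
    multivariate hypergeometric, deterministic for a given seed.
    """
    if table.mode != "counts":
        raise ValueError("rarefaction requires counts mode")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    out = table.values.copy()
    for i in range(out.shape[0]):
        counts = np.round(out[i]).astype(np.int64)
        total = int(counts.sum())
        if total > depth:
            out[i] = rng.multivariate_hypergeometric(counts, depth)
    return AbundanceTable(table.sample_ids, table.otu_ids, out, "counts", table.taxonomy)


@dataclass(frozen=True)
class ScfaProfile:
    """Per-sample SCFA concentrations (umol/g wet feces) plus pH and moisture."""

    sample_id: str
    acetate: float
    propionate: float
    butyrate: float
    isobutyrate: float
    isovalerate: float
    ph: float | None = None
    moisture: float | None = None

    def __post_init__(self) -> None:
        for name in SCFA_COLUMNS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} concentration must be non-negative")
        if self.moisture is not None and not 0 <= self.moisture <= 1:
            raise ValueError("moisture must lie in [0, 1]")


def read_scfa_table(path) -> dict[str, ScfaProfile]:
    """Read a TSV of SCFA concentrations keyed by sample id.

    Requires the five named SCFA columns; unknown extra columns (other than
    optional ``ph`` / ``moisture``) are ignored with a warning.
    """
    frame = pd.read_csv(path, sep="\t")
    if "sample_id" not in frame.columns:
        raise FormatError("SCFA table missing 'sample_id' column")
    missing = set(SCFA_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"SCFA table missing columns: {sorted(missing)}")
    known = {"sample_id", "ph", "moisture", *SCFA_COLUMNS}
    extra = [c for c in frame.columns if c not in known]
    if extra:
        warnings.warn(f"ignoring unknown SCFA table columns: {extra}", stacklevel=2)
    profiles: dict[str, ScfaProfile] = {}
    for _, row in frame.iterrows():
        sid = str(row["sample_id"])
        profiles[sid] = ScfaProfile(
            sample_id=sid,
            acetate=float(row["acetate"]),
            propionate=float(row["propionate"]),
            butyrate=float(row["butyrate"]),
            isobutyrate=float(row["isobutyrate"]),
            isovalerate=float(row["isovalerate"]),
            ph=float(row["ph"]) if "ph" in frame.columns else None,
            moisture=float(row["moisture"]) if "moisture" in frame.columns else None,
        )
    return profiles


def write_scfa_table(profiles: dict[str, ScfaProfile], path) -> None:
    rows = []
    for sid, p in profiles.items():
        row = {"sample_id": sid}
        row.update({name: getattr(p, name) for name in SCFA_COLUMNS})
        if p.ph is not None:
            row["ph"] = p.ph
        if p.moisture is not None:
            row["moisture"] = p.moisture
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class StoolDiary:
    """Weekly stool scores BL..W6 on a 5-point (0-4) hedonic scale."""

    subject_id: str
    consistency: tuple[float, ...]
    frequency: tuple[float, ...]

    def __post_init__(self) -> None:
        for scores in (self.consistency, self.frequency):
            for s in scores:
                if not np.isnan(s) and not 0 <= s <= 4:
                    raise ValueError("stool scores must lie in [0, 4]")


def read_stool_diary_table(path) -> dict[str, StoolDiary]:
    """Read a TSV with one row per (subject, measure) and weekly score columns."""
    frame = pd.read_csv(path, sep="\t")
    week_cols = [c for c in frame.columns if c.startswith("week")]
    if not week_cols or {"subject_id", "measure"} - set(frame.columns):
        raise FormatError("stool diary needs subject_id, measure, week* columns")
    week_cols = sorted(week_cols, key=lambda c: int(c.replace("week", "")))
    diaries: dict[str, dict[str, tuple[float, ...]]] = {}
    for _, row in frame.iterrows():
        sid = str(row["subject_id"])
        scores = tuple(float(row[c]) for c in week_cols)
        diaries.setdefault(sid, {})[str(row["measure"])] = scores
    return {
        sid: StoolDiary(sid, d.get("consistency", ()), d.get("frequency", ()))
        for sid, d in diaries.items()
    }


def write_stool_diary_table(diaries: dict[str, StoolDiary], path) -> None:
    rows = []
    for sid, diary in diaries.items():
        for measure in ("consistency", "frequency"):
            scores = getattr(diary, measure)
            row = {"subject_id": sid, "measure": measure}
            row.update({f"week{i}": s for i, s in enumerate(scores)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
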