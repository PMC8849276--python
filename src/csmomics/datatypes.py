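"""Core containers shared by all analysis stages.

The subject table and the per-block analyte matrices are pandas objects
(indexed by ``subject_id``); thin dataclasses wrap them with the design
invariants of a 1:1 matched case-control study: every matched pair joins
exactly one nonsurvivor (NS) and one survivor (S), and all blocks share
the subject ordering of the metadata table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

OUTCOMES = ("NS", "S", "HC")
BLOCKS = ("metabolite", "protein", "cytokine")

#: analyte class labels used for network node colouring and ratio definitions
ANALYTE_CLASSES = (
    "amino acid", "organic acid", "biogenic amine", "acylcarnitine",
    "lysoPC", "PC", "SM", "hexose", "protein", "cytokine",
)


class ValidationError(ValueError):
    """Raised when a container violates a design invariant."""


@dataclass
class SubjectRecord:
    """One study subject's metadata row.

    ``pair_id`` is present iff the subject is a matched NS or S member;
    healthy-community (HC) reference subjects are unmatched.
    """

    subject_id: str
    outcome: str
    pair_id: str | None
    age_months: float
    muac_cm: float
    hiv: str
    edema: bool
    whz: float
    site: str
    batch: str
    time_to_event_days: int
    clinical_flags: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.outcome == "HC" and self.pair_id is not None:
            raise ValidationError(
                f"subject {self.subject_id}: HC reference subjects are never matched"
            )
        if self.time_to_event_days < 1:
            raise ValidationError(f"subject {self.subject_id}: time_to_event_days < 1")

    @classmethod
    def from_row(cls, row: pd.Series) -> "SubjectRecord":
        flags = {c[5:]: bool(row[c]) for c in row.index if c.startswith("flag_")}
        pair = row.get("pair_id")
        if pd.isna(pair):
            pair = None
        return cls(
            subject_id=str(row.name),
            outcome=row["outcome"],
            pair_id=pair,
            age_months=float(row["age_months"]),
            muac_cm=float(row["muac_cm"]),
            hiv=row["hiv"],
            edema=bool(row["edema"]),
            whz=float(row["whz"]),
            site=row["site"],
            batch=str(row["batch"]),
            time_to_event_days=int(row["time_to_event_days"]),
            clinical_flags=flags,
        )


@dataclass
class AnalyteMatrix:
    """A subjects x analytes concentration block on the raw scale.

    Parameters
    ----------
    block : {"metabolite", "protein", "cytokine"}
    values : DataFrame, subjects in rows, analytes in columns, raw
        concentrations (µM for metabolites, reporter intensity for
        proteins, pg/mL for cytokines). Non-detected/missing cells hold
        the last observed draw but are flagged in ``mask``.
    mask : boolean DataFrame, same shape; True marks a missing or
        below-LOD cell.
    classes : analyte_id -> class label.
    lod : per-analyte limit of detection (metabolites only).
    """

    block: str
    values: pd.DataFrame
    mask: pd.DataFrame
    classes: pd.Series
    lod: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ValidationError(f"unknown block {self.block!r}")
        if self.mask.shape != self.values.shape:
            raise ValidationError("mask and values must have identical shape")
        if not self.values.columns.equals(self.mask.columns) or not self.values.index.equals(
            self.mask.index
        ):
            raise ValidationError("mask and values must share index/columns")
        missing_cls = [a for a in self.values.columns if a not in self.classes.index]
        if missing_cls:
            raise ValidationError(f"analytes without class label: {missing_cls[:5]}")
        vals = self.values.to_numpy(float)
        if np.any(vals < 0):
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative concentration at subject {self.values.index[r]!r}, "
                f"analyte {self.values.columns[c]!r}"
            )

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def observed(self) -> pd.DataFrame:
        """Values with masked cells set to NaN."""
        return self.values.mask(self.mask)

    def subset_analytes(self, analytes: Sequence[str]) -> "AnalyteMatrix":
        analytes = list(analytes)
        return AnalyteMatrix(
            block=self.block,
            values=self.values[analytes].copy(),
            mask=self.mask[analytes].copy(),
            classes=self.classes.loc[analytes].copy(),
            lod=None if self.lod is None else self.lod.reindex(analytes),
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the synthetic generator."""

    differential_set: list[str]
    effect_sizes: dict[str, float]
    correlation_shift_pairs: list[tuple[str, str, float, float]]
    seed: int

    def __post_init__(self) -> None:
        missing = set(self.differential_set) - set(self.effect_sizes)
        if missing:
            raise ValidationError(f"differential analytes without effect size: {sorted(missing)[:5]}")
        for a, b, r_s, r_ns in self.correlation_shift_pairs:
            if not (abs(r_s) < 1 and abs(r_ns) < 1):
                raise ValidationError(f"correlation shift ({a},{b}) needs |r| < 1")


@dataclass
class CohortDataset:
    """Subject metadata plus per-block analyte matrices and QC replicates."""

    subjects: pd.DataFrame
    matrices: dict[str, AnalyteMatrix]
    qc_samples: pd.DataFrame | None = None
    truth: SyntheticTruth | None = None

    def __post_init__(self) -> None:
        validate_subjects(self.subjects)
        for block, mat in self.matrices.items():
            if mat.block != block:
                raise ValidationError(f"matrix under key {block!r} has block {mat.block!r}")
            if not mat.values.index.equals(self.subjects.index):
                raise ValidationError(f"{block} matrix subject ordering differs from metadata")
        if self.qc_samples is not None and "metabolite" in self.matrices:
            met = set(self.matrices["metabolite"].analyte_ids)
            if not met <= set(self.qc_samples.columns):
                missing = sorted(met - set(self.qc_samples.columns))
                raise ValidationError(f"qc_samples missing metabolites: {missing[:5]}")

    @property
    def pair_set(self) -> "PairSet":
        return PairSet.from_subjects(self.subjects)

    def subject_records(self) -> list[SubjectRecord]:
        return [SubjectRecord.from_row(row) for _, row in self.subjects.iterrows()]


def validate_subjects(subjects: pd.DataFrame) -> None:
    """Enforce the matched-design invariants on a metadata table."""
    bad = subjects.index[~subjects["outcome"].isin(OUTCOMES)]
    if len(bad):
        raise ValidationError(f"unknown outcome for subjects {list(bad[:5])}")
    matched = subjects[subjects["outcome"].isin(["NS", "S"])]
    hc = subjects[subjects["outcome"] == "HC"]
    if "pair_id" in subjects.columns:
        if hc["pair_id"].notna().any():
            raise ValidationError("HC subjects must not carry a pair_id")
        paired = matched[matched["pair_id"].notna()]
        orphans = []
        for pid, grp in paired.groupby("pair_id"):
            if sorted(grp["outcome"]) != ["NS", "S"]:
                orphans.append(pid)
        if orphans:
            raise ValidationError(f"pair_ids without exactly one NS and one S: {sorted(orphans)[:10]}")
    if (subjects["time_to_event_days"] < 1).any():
        raise ValidationError("time_to_event_days must be >= 1")


@dataclass
class PairSet:
    """The 1:1 case-control matching structure.

    ``pairs`` lists ``(case_id, control_id, distance)``; distance is NaN
    for pairs constructed directly (e.g. by the synthetic generator)
    rather than by propensity matching.
    """

    pairs: list[tuple[str, str, float]]
    unmatched: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for case, control, _ in self.pairs:
            for s in (case, control):
                if s in seen:
                    raise ValidationError(f"subject {s!r} appears in more than one pair")
                seen.add(s)

    @classmethod
    def from_subjects(cls, subjects: pd.DataFrame) -> "PairSet":
        matched = subjects[subjects.get("pair_id").notna()] if "pair_id" in subjects else subjects.iloc[:0]
        pairs = []
        for pid, grp in matched.groupby("pair_id"):
            case = grp.index[grp["outcome"] == "NS"][0]
            control = grp.index[grp["outcome"] == "S"][0]
            pairs.append((case, control, float("nan")))
        pairs.sort()
        unmatched = [s for s in subjects.index if s not in {x for p in pairs for x in p[:2]}]
        return cls(pairs=pairs, unmatched=unmatched)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def case_ids(self) -> list[str]:
        return [p[0] for p in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [p[1] for p in self.pairs]

    def member_ids(self) -> list[str]:
        """All paired subjects, cases then controls pair by pair."""
        out = []
        for case, control, _ in self.pairs:
            out.extend([case, control])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["case_id", "control_id", "distance"])
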