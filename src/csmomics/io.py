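"""Flat-file interchange for cohort datasets.

One TSV per analyte block (subjects in rows, analytes in columns, ``NA``
for non-detected/missing cells), one metadata TSV, per-block class-label
TSVs, a metabolite LOD TSV, a QC-sample TSV and a ``truth.json`` when
the dataset is synthetic. The round trip is lossless for observed
values, masks, metadata, LODs and ground truth; cells written as ``NA``
read back as NaN under a True mask.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AnalyteMatrix, CohortDataset, SyntheticTruth, ValidationError, validate_subjects

__all__ = ["write_cohort", "read_cohort"]

_META_COLS = [
    "outcome", "pair_id", "age_months", "muac_cm", "hiv", "edema", "whz",
    "site", "batch", "time_to_event_days",
]


def write_cohort(dataset: CohortDataset, directory: str | Path) -> list[Path]:
    """Write ``dataset`` as flat TSV/JSON files; returns the paths written."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    meta = dataset.subjects.copy()
    p = d / "subjects.tsv"
    meta.to_csv(p, sep="\t", na_rep="NA")
    written.append(p)

    blocks = sorted(dataset.matrices)
    for block in blocks:
        mat = dataset.matrices[block]
        p = d / f"{block}.tsv"
        mat.observed().to_csv(p, sep="\t", na_rep="NA")
        written.append(p)
        p = d / f"{block}.classes.tsv"
        mat.classes.rename("class").to_csv(p, sep="\t")
        written.append(p)
        if mat.lod is not None:
            p = d / f"{block}.lod.tsv"
            mat.lod.rename("lod").to_csv(p, sep="\t")
            written.append(p)

    if dataset.qc_samples is not None:
        p = d / "qc_samples.tsv"
        dataset.qc_samples.to_csv(p, sep="\t")
        written.append(p)

    if dataset.truth is not None:
        p = d / "truth.json"
        t = dataset.truth
        payload = {
            "differential_set": t.differential_set,
            "effect_sizes": t.effect_sizes,
            "correlation_shift_pairs": [list(x) for x in t.correlation_shift_pairs],
            "seed": t.seed,
        }
        p.write_text(json.dumps(payload, indent=1))
        written.append(p)

    manifest = {"blocks": blocks, "qc_samples": dataset.qc_samples is not None,
                "truth": dataset.truth is not None}
    p = d / "dataset.json"
    p.write_text(json.dumps(manifest, indent=1))
    written.append(p)
    return written


def _read_matrix(d: Path, block: str) -> AnalyteMatrix:
    path = d / f"{block}.tsv"
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    values.index = values.index.astype(str)
    bad = np.argwhere(values.to_numpy(float) < 0)
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"{path.name}: negative concentration at row {values.index[r]!r}, "
            f"column {values.columns[c]!r}"
        )
    mask = values.isna()
    classes = pd.read_csv(d / f"{block}.classes.tsv", sep="\t", index_col=0)["class"]
    lod = None
    lod_path = d / f"{block}.lod.tsv"
    if lod_path.exists():
        lod = pd.read_csv(lod_path, sep="\t", index_col=0)["lod"]
    return AnalyteMatrix(block=block, values=values, mask=mask, classes=classes, lod=lod)


def read_cohort(directory: str | Path) -> CohortDataset:
    """Read a dataset written by :func:`write_cohort`, validating invariants."""
    d = Path(directory)
    manifest_path = d / "dataset.json"
    if not manifest_path.exists():
        raise ValidationError(f"{d}: no dataset.json manifest found")
    manifest = json.loads(manifest_path.read_text())

    subjects = pd.read_csv(d / "subjects.tsv", sep="\t", index_col=0,
                           na_values=["NA"], keep_default_na=False)
    subjects.index = subjects.index.astype(str)
    if "pair_id" in subjects.columns:
        subjects["pair_id"] = subjects["pair_id"].where(subjects["pair_id"].notna(), None)
    if "edema" in subjects.columns:
        subjects["edema"] = subjects["edema"].astype(str).str.lower().isin(["true", "1"])
    for c in subjects.columns:
        if c.startswith("flag_"):
            subjects[c] = subjects[c].astype(str).str.lower().isin(["true", "1"])
    validate_subjects(subjects)

    matrices = {}
    for block in manifest["blocks"]:
        mat = _read_matrix(d, block)
        if not mat.values.index.equals(subjects.index):
            extra = set(mat.values.index) ^ set(subjects.index)
            raise ValidationError(
                f"{block}.tsv subject ids disagree with subjects.tsv: {sorted(extra)[:5]}"
            )
        matrices[block] = mat

    qc = None
    if manifest.get("qc_samples"):
        qc = pd.read_csv(d / "qc_samples.tsv", sep="\t", index_col=0)

    truth = None
    if manifest.get("truth"):
        t = json.loads((d / "truth.json").read_text())
        truth = SyntheticTruth(
            differential_set=t["differential_set"],
            effect_sizes=t["effect_sizes"],
            correlation_shift_pairs=[tuple(x) for x in t["correlation_shift_pairs"]],
            seed=t["seed"],
        )
    return CohortDataset(subjects=subjects, matrices=matrices, qc_samples=qc, truth=truth)
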