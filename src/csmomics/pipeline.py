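"""End-to-end orchestration of the discovery workflow.

Stages run in order — simulate (or load), preprocess, match, summarize,
univariate (+ ratios), stability, union, plsda, diffcorr, snf — each
reading and writing flat TSV/JSON artifacts under the output directory.
A manifest records every parameter, derived seed and file hash, so two
runs with the same config and master seed produce byte-identical
numeric artifacts; with ``resume=True`` completed stages (their outputs
already on disk and hashes in the manifest) are skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .datatypes import CohortDataset, PairSet, ValidationError
from .diffcorr import build_differential_network, cluster_heatmap, group_correlations, pooled_scfa_analysis
from .matching import balance_diagnostics
from .plsda import MultilevelPLSDA
from .preprocess import (
    ProcessedMatrix,
    autoscale,
    batch_correct,
    cv_detection_filter,
    impute_lod,
    knn_impute,
    protein_missingness_filter,
    transform_autoscale,
)
from .simulate import GeneratorConfig, generate_cohort
from .snf import SimilarityNetworkFusion, deviation_zscores, cluster_characterization
from .stability import StabilitySelection, union_differential
from .summary import summarize_cohort
from .univariate import BUILTIN_RATIOS, compute_ratios, screen_analytes

__all__ = ["PipelineConfig", "run_pipeline", "residualize"]

STAGES = ["simulate", "preprocess", "match", "summarize", "univariate",
          "stability", "plsda", "diffcorr", "snf"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; one master seed derives every
    module seed."""

    outdir: str = "results"
    seed: int = 0
    input_dir: str | None = None          # load instead of simulating
    simulate: dict = field(default_factory=dict)   # GeneratorConfig overrides

    cv_max: float = 0.30
    detect_min: float = 0.80
    max_missing: float = 0.20
    knn_k: int = 10

    stability_B: int = 200
    stability_alpha: float = 0.75
    stability_threshold: float = 0.70
    stability_n_lambda: int = 100
    stability_blocks: tuple[str, ...] = ("metabolite", "protein")

    plsda_components: int = 2
    plsda_folds: int = 10
    plsda_repeats: int = 50

    snf_K: int = 20
    snf_mu: float = 0.5
    snf_t: int = 20

    adjust_for: str | None = None         # None | "edema" | "whz"
    residualize: bool = False

    def validate(self) -> None:
        if self.adjust_for not in (None, "edema", "whz"):
            raise ValidationError("adjust_for must be None, 'edema' or 'whz'")
        for nm, lo, hi in [("cv_max", 0, 1), ("detect_min", 0, 1), ("max_missing", 0, 1),
                           ("stability_alpha", 0, 1), ("stability_threshold", 0, 1)]:
            v = getattr(self, nm)
            if not (lo <= v <= hi):
                raise ValidationError(f"{nm}={v} outside [{lo}, {hi}]")
        if self.stability_B < 1 or self.plsda_repeats < 1:
            raise ValidationError("iteration counts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "stability_blocks" in payload:
            payload["stability_blocks"] = tuple(payload["stability_blocks"])
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def module_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(len(STAGES))
        return {s: int(v % (2**31)) for s, v in zip(STAGES, state)}


def residualize(matrix: ProcessedMatrix | pd.DataFrame, covariate: pd.Series) -> ProcessedMatrix:
    """Regress each analyte on the covariate (OLS with intercept),
    keep residuals, re-autoscale."""
    df = matrix.values if isinstance(matrix, ProcessedMatrix) else matrix
    cov = covariate.reindex(df.index).astype(float)
    if cov.isna().any():
        raise ValidationError("covariate missing for some subjects")
    if cov.std(ddof=1) == 0:
        raise ValidationError("constant covariate cannot be residualized")
    x = cov.to_numpy()
    xc = x - x.mean()
    v = df.to_numpy(float)
    vc = v - v.mean(axis=0)
    beta = (xc @ xc) and (xc @ vc) / (xc @ xc)
    resid = vc - np.outer(xc, beta)
    # numerically exhausted columns (analyte collinear with covariate)
    sd = resid.std(axis=0, ddof=1)
    dead = sd < 1e-10 * np.maximum(vc.std(axis=0, ddof=1), 1.0)
    if dead.any():
        import warnings
        dropped = list(df.columns[dead])
        warnings.warn(f"dropping zero-variance residual columns: {dropped[:5]}", stacklevel=2)
        resid = resid[:, ~dead]
        df = df.loc[:, df.columns[~dead]]
    return autoscale(pd.DataFrame(resid, index=df.index, columns=df.columns),
                     provenance=[{"step": "residualize", "covariate": covariate.name}])


# ---------------------------------------------------------------------------
# manifest helpers


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig) -> None:
        self.path = outdir / "manifest.json"
        self.data = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(config).items()},
            "seeds": config.module_seeds(),
            "stages": {},
        }

    def record(self, stage: str, files: list[Path], outdir: Path) -> None:
        self.data["stages"][stage] = {
            str(f.relative_to(outdir)): _sha256(f) for f in sorted(files)
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))

    def stage_done(self, stage: str, outdir: Path) -> bool:
        rec = self.data["stages"].get(stage)
        if not rec:
            return False
        return all((outdir / f).exists() and _sha256(outdir / f) == h for f, h in rec.items())

    @classmethod
    def load_existing(cls, outdir: Path, config: PipelineConfig) -> "_Manifest":
        m = cls(outdir, config)
        if m.path.exists():
            old = json.loads(m.path.read_text())
            if old.get("config") == m.data["config"]:
                m.data["stages"] = old.get("stages", {})
        return m


def _write_json(path: Path, payload) -> Path:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=_jsonify))
    return path


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute every stage; returns the in-memory results bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.module_seeds()
    manifest = _Manifest.load_existing(outdir, config) if resume else _Manifest(outdir, config)
    results: dict = {"outdir": outdir, "seeds": seeds}

    # --- simulate / load -------------------------------------------------
    sim_dir = outdir / "cohort"
    if config.input_dir is not None:
        if not Path(config.input_dir).exists():
            raise ValidationError(f"input_dir {config.input_dir} does not exist")
        dataset = cio.read_cohort(config.input_dir)
    elif resume and manifest.stage_done("simulate", outdir):
        dataset = cio.read_cohort(sim_dir)
    else:
        gen_cfg = GeneratorConfig(**{"seed": seeds["simulate"], **config.simulate})
        dataset = generate_cohort(gen_cfg)
        files = cio.write_cohort(dataset, sim_dir)
        manifest.record("simulate", files, outdir)
    results["dataset"] = dataset
    pairs = dataset.pair_set
    if pairs.n_pairs == 0:
        raise ValidationError("cohort has no matched pairs")
    subjects = dataset.subjects
    groups = subjects["outcome"]

    # --- preprocess -------------------------------------------------------
    pp_dir = outdir / "preprocess"
    pp_dir.mkdir(exist_ok=True)
    processed: dict[str, ProcessedMatrix] = {}
    raw_clean: dict[str, pd.DataFrame] = {}
    qc_reports = {}
    files = []
    paired_ids = pairs.member_ids()
    for block, mat in dataset.matrices.items():
        mat = _subset_subjects(mat, paired_ids)  # paired subjects only
        if block == "metabolite":
            if dataset.qc_samples is None:
                raise ValidationError("metabolite block needs QC samples")
            mat, rep = cv_detection_filter(mat, dataset.qc_samples, groups,
                                           cv_max=config.cv_max, detect_min=config.detect_min)
            mat = impute_lod(mat)
        elif block == "protein":
            mat, rep = protein_missingness_filter(mat, max_missing=config.max_missing)
            mat = knn_impute(mat, k=config.knn_k)
            mat = batch_correct(mat, subjects["batch"], shrinkage=True)
        else:
            mat, rep = cv_detection_filter(
                mat, _pseudo_qc(mat), groups, cv_max=np.inf, detect_min=config.detect_min
            )
            mat = _drop_masked(mat)
        qc_reports[block] = rep
        raw_clean[block] = mat.values
        processed[block] = transform_autoscale(mat)
        files.append(_df_tsv(pp_dir / f"raw_{block}.tsv", mat.values))
        files.append(_df_tsv(pp_dir / f"processed_{block}.tsv", processed[block].values))
        files.append(_df_tsv(pp_dir / f"qc_report_{block}.tsv", rep.table))
        files.append(_write_json(pp_dir / f"qc_summary_{block}.json", rep.summary()))
    manifest.record("preprocess", files, outdir)
    results.update(processed=processed, raw=raw_clean, qc_reports=qc_reports)

    if config.residualize:
        cov = _covariate(subjects, config.adjust_for or "edema").reindex(paired_ids)
        processed = {b: residualize(p, cov) for b, p in processed.items()}
        results["processed"] = processed

    # --- match (validate the design; diagnostics on the matched sample) ---
    mt_dir = outdir / "match"
    mt_dir.mkdir(exist_ok=True)
    balance = balance_diagnostics(pairs, subjects)
    files = [
        _df_tsv(mt_dir / "pairs.tsv", pairs.to_frame()),
        _df_tsv(mt_dir / "balance.tsv", balance),
    ]
    manifest.record("match", files, outdir)
    results["balance"] = balance

    # --- summarize --------------------------------------------------------
    summary = summarize_cohort(subjects)
    files = [_df_tsv(outdir / "cohort_summary.tsv", summary.reset_index())]
    manifest.record("summarize", files, outdir)
    results["cohort_summary"] = summary

    # --- univariate + ratios ----------------------------------------------
    uv_dir = outdir / "univariate"
    uv_dir.mkdir(exist_ok=True)
    adjust = None
    if config.adjust_for:
        adjust = _covariate(subjects, config.adjust_for)
    univ = {}
    files = []
    for block, proc in processed.items():
        rule = ("q", 0.01) if block == "metabolite" else ("p", 0.05)
        univ[block] = screen_analytes(proc, pairs, raw=raw_clean[block], adjust_for=adjust,
                                      sig_on=rule[0], sig_threshold=rule[1])
        files.append(_df_tsv(uv_dir / f"univariate_{block}.tsv", univ[block]))
    ratio_defs = [rd for rd in BUILTIN_RATIOS
                  if set(rd.numerator) | set(rd.denominator) - {"unit"}
                  <= set(raw_clean["metabolite"].columns)]
    if ratio_defs:
        ratios = compute_ratios(raw_clean["metabolite"], ratio_defs)
        univ["ratios"] = screen_analytes(transform_autoscale(ratios), pairs,
                                         raw=ratios.values, adjust_for=adjust,
                                         sig_on="q", sig_threshold=0.05)
        files.append(_df_tsv(uv_dir / "ratios.tsv", ratios.values))
        files.append(_df_tsv(uv_dir / "univariate_ratios.tsv", univ["ratios"]))
    manifest.record("univariate", files, outdir)
    results["univariate"] = univ

    # --- stability selection + union ---------------------------------------
    st_dir = outdir / "stability"
    st_dir.mkdir(exist_ok=True)
    profiles, differential = {}, {}
    files = []
    for bi, block in enumerate(config.stability_blocks):
        model = StabilitySelection(
            processed[block], pairs, B=config.stability_B, alpha=config.stability_alpha,
            threshold=config.stability_threshold, n_lambda=config.stability_n_lambda,
            seed=seeds["stability"] + bi,
        )
        prof = model.fit()
        profiles[block] = prof
        differential[block] = union_differential(univ[block], prof)
        files.append(_df_tsv(st_dir / f"selection_{block}.tsv", prof.summary()))
        files.append(_write_json(
            st_dir / f"differential_{block}.json",
            {"analytes": differential[block].analyte_ids,
             "provenance": differential[block].provenance},
        ))
    manifest.record("stability", files, outdir)
    results.update(profiles=profiles, differential=differential)

    # --- multilevel PLS-DA on each block's differential set ----------------
    pl_dir = outdir / "plsda"
    pl_dir.mkdir(exist_ok=True)
    plsda_res = {}
    files = []
    for block, dset in differential.items():
        if len(dset) < 2:
            continue
        sub = processed[block].values[dset.analyte_ids]
        model = MultilevelPLSDA(sub, pairs, n_components=config.plsda_components)
        fitres = model.fit()
        perf = model.cross_validate(n_folds=config.plsda_folds, n_repeats=config.plsda_repeats,
                                    seed=seeds["plsda"])
        plsda_res[block] = {"fit": fitres, "cv": perf}
        files.append(_df_tsv(pl_dir / f"scores_{block}.tsv", fitres.scores))
        files.append(_df_tsv(pl_dir / f"correlation_circle_{block}.tsv", fitres.correlation_circle))
        files.append(_write_json(pl_dir / f"performance_{block}.json",
                                 {"fit": fitres.summary(), "cv": perf.summary()}))
    manifest.record("plsda", files, outdir)
    results["plsda"] = plsda_res

    # --- differential correlation network ----------------------------------
    dc_dir = outdir / "diffcorr"
    dc_dir.mkdir(exist_ok=True)
    cross_cols, classes = [], {}
    for block in processed:
        ids = (differential[block].analyte_ids if block in differential
               else processed[block].analyte_ids)
        cross_cols.append(processed[block].values[ids])
        cls = dataset.matrices[block].classes
        classes.update({a: cls.get(a, block) for a in ids})
    cross = pd.concat(cross_cols, axis=1)
    class_series = pd.Series(classes)
    corr = group_correlations(cross, groups)
    network = build_differential_network(corr, classes=class_series)
    heat = cluster_heatmap(cross, classes=class_series)
    files = [
        _df_tsv(dc_dir / "edges.tsv", network.edges),
        _df_tsv(dc_dir / "nodes.tsv", network.nodes),
        _df_tsv(dc_dir / "heatmap_correlation.tsv", heat["correlation"]),
        _write_json(dc_dir / "heatmap_tree.json",
                    {"order": heat["order"], "linkage": heat["linkage"].tolist()}),
    ]
    scfa = None
    met_cols = set(raw_clean["metabolite"].columns)
    if {"propionate", "isobutyrate", "butyrate"} <= met_cols and \
            "cytokine" in raw_clean and "IL8" in raw_clean["cytokine"].columns:
        scfa = pooled_scfa_analysis(raw_clean["metabolite"], raw_clean["cytokine"])
        files.append(_write_json(dc_dir / "scfa_il8.json",
                                 {"r": scfa["r"], "p": scfa["p"],
                                  "crosstab": scfa["crosstab"].to_numpy().tolist()}))
    manifest.record("diffcorr", files, outdir)
    results.update(network=network, heatmap=heat, scfa=scfa)

    # --- similarity network fusion -----------------------------------------
    snf_dir = outdir / "snf"
    snf_dir.mkdir(exist_ok=True)
    clinical = _clinical_view(subjects.loc[paired_ids])
    views: dict = {"clinical": (clinical, "gower")}
    for block, proc in processed.items():
        views[block] = (proc.values, "euclidean_scaled")
    snf_model = SimilarityNetworkFusion(views, K=min(config.snf_K, len(paired_ids) - 1),
                                        mu=config.snf_mu, t=config.snf_t,
                                        seed=seeds["snf"])
    snf_res = snf_model.fit()
    zs = deviation_zscores(pd.concat([p.values for p in processed.values()], axis=1),
                           subjects.loc[paired_ids])
    charac = cluster_characterization(
        pd.concat([p.values for p in processed.values()], axis=1),
        snf_res.labels[2], subjects["outcome"].reindex(paired_ids),
    )
    files = [
        _df_tsv(snf_dir / "fused.tsv", snf_res.fused),
        _df_tsv(snf_dir / "clusters.tsv",
                pd.DataFrame({f"k{k}": lab for k, lab in snf_res.labels.items()})),
        _write_json(snf_dir / "concordance.json", snf_res.concordance),
        _df_tsv(snf_dir / "deviation_zscores.tsv", zs),
        _write_json(snf_dir / "cluster_characterization.json",
                    {c: {"n": v["n"], "composition": v["composition"],
                         "top_features": v["top_features"].round(6).to_dict()}
                     for c, v in charac.items()}),
    ]
    manifest.record("snf", files, outdir)
    results.update(snf=snf_res, deviation_zscores=zs, cluster_characterization=charac)
    return results


# ---------------------------------------------------------------------------
# small helpers


def _df_tsv(path: Path, df: pd.DataFrame) -> Path:
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")
    return path


def _subset_subjects(mat, subject_ids):
    from .datatypes import AnalyteMatrix
    return AnalyteMatrix(
        block=mat.block,
        values=mat.values.loc[subject_ids],
        mask=mat.mask.loc[subject_ids],
        classes=mat.classes,
        lod=mat.lod,
    )


def _pseudo_qc(mat) -> pd.DataFrame:
    """Constant pseudo-QC for blocks without QC samples: the CV rule
    never fires and only the detection rule applies."""
    return pd.DataFrame(1.0, index=["QC01", "QC02", "QC03"], columns=mat.values.columns)


def _drop_masked(mat):
    """Replace residual non-detects by the analyte's minimum observed
    value (cytokine block after detection filtering)."""
    from .datatypes import AnalyteMatrix
    obs = mat.observed()
    filled = obs.fillna(obs.min())
    return AnalyteMatrix(
        block=mat.block,
        values=filled,
        mask=pd.DataFrame(False, index=filled.index, columns=filled.columns),
        classes=mat.classes,
        lod=mat.lod,
    )


def _covariate(subjects: pd.DataFrame, name: str) -> pd.Series:
    if name == "edema":
        return subjects["edema"].astype(float)
    if name == "whz":
        return subjects["whz"].astype(float)
    raise ValidationError(f"unknown covariate {name!r}")


def _clinical_view(subjects: pd.DataFrame) -> pd.DataFrame:
    cols = ["age_months", "muac_cm", "whz", "edema", "hiv", "site"]
    cols += [c for c in subjects.columns if c.startswith("flag_")]
    return subjects[cols].copy()
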