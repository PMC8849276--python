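"""Synthetic matched case-control multiomics cohort with planted ground truth.

The generator emulates the statistical structure of a hospital cohort of
children with complicated severe malnutrition: 92 nonsurvivor/survivor
(NS/S) pairs measured on three blocks — targeted metabolites (206,
Biocrates-style panel plus organic acids), untargeted TMT proteins (229)
and Luminex cytokines (29) — with

* log-normal concentrations and class-structured correlation,
* a shared latent pair effect (the matched design),
* a planted differential subset with NS-S mean shifts delta expressed in
  within-group SD units on the log10 scale,
* group-specific correlation for selected analyte pairs (a Gaussian
  copula per group), giving the differential-correlation stage a
  recoverable truth,
* left-censoring at a per-analyte limit of detection, missing-at-random
  protein dropout, and additive TMT-batch shifts on the protein block,
* QC replicate samples whose per-analyte coefficient of variation is set
  exactly, so a configured fraction of metabolites fails the CV<30% rule,
* clinical covariates/flags whose prevalence differs by outcome, giving
  the clinical view weak outcome signal.

Nonsurvivors who die earlier carry proportionally larger shifts (a
severity gradient over time-to-death strata), normalised so the average
planted effect remains delta.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AnalyteMatrix, CohortDataset, SyntheticTruth, ValidationError

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "generate_qc_samples",
    "generate_unmatched_pool",
    "metabolite_panel",
    "protein_panel",
    "cytokine_panel",
]

# ---------------------------------------------------------------------------
# analyte panels

_AMINO_ACIDS = [
    "alanine", "arginine", "asparagine", "aspartate", "citrulline", "cystine",
    "glutamine", "glutamate", "glycine", "histidine", "isoleucine", "leucine",
    "lysine", "methionine", "ornithine", "phenylalanine", "proline", "serine",
    "threonine", "tryptophan", "tyrosine", "valine",
]  # 22

_ORGANIC_ACIDS = [
    "propionate", "isobutyrate", "butyrate", "pyruvate", "lactate", "fumarate",
    "succinate", "citrate", "alpha-ketoglutarate", "beta-hydroxybutyrate",
    "homovanillate", "urate", "methylmalonate", "hippurate",
    "p-hydroxyphenylacetate", "5-hydroxyindoleacetate", "isovalerate", "oxalate",
]  # 18

_BIOGENIC_AMINES = [
    "kynurenine", "taurine", "creatinine", "serotonin", "putrescine",
    "spermidine", "spermine", "sarcosine", "ADMA", "SDMA", "carnosine",
    "histamine", "dopamine", "DOPA", "acetylornithine", "trans-hydroxyproline",
    "methionine-sulfoxide", "alpha-aminoadipate", "nitrotyrosine",
    "phenylethylamine",
]  # 20

_ACYLCARNITINES = [
    "C0", "C2", "C3", "C4", "C5", "C6", "C8", "C10", "C12", "C14", "C16", "C18",
    "C3:1", "C4:1", "C5:1", "C6:1", "C10:1", "C10:2", "C12:1", "C14:1",
    "C14:2", "C16:1", "C16:2", "C18:1", "C18:2", "C3-OH", "C4-OH", "C5-OH",
    "C14:1-OH", "C16-OH", "C16:1-OH", "C18:1-OH", "C5-DC", "C6-DC", "C12-DC",
    "C5-M-DC", "C7-DC", "C9", "C5:1-DC", "C16:2-OH",
]  # 40

_LYSOPCS = [
    "lysoPC a C14:0", "lysoPC a C16:0", "lysoPC a C16:1", "lysoPC a C17:0",
    "lysoPC a C18:0", "lysoPC a C18:1", "lysoPC a C18:2", "lysoPC a C20:3",
    "lysoPC a C20:4", "lysoPC a C24:0", "lysoPC a C26:0", "lysoPC a C26:1",
    "lysoPC a C28:0", "lysoPC a C28:1",
]  # 14

_SMS = [
    "SM C16:0", "SM C16:1", "SM C18:0", "SM C18:1", "SM C20:2", "SM C24:0",
    "SM C24:1", "SM C26:0", "SM C26:1", "SM (OH) C14:1", "SM (OH) C16:1",
    "SM (OH) C22:1", "SM (OH) C22:2", "SM (OH) C24:1", "SM C22:3",
]  # 15

_NAMED_PROTEINS = [
    "CRP", "S100A8", "S100A9", "VWF", "AGT", "HRG", "C4BPB", "SERPINC1",
    "SERPIND1", "VTDB", "F10", "F11", "MST1", "QSOX1", "ALB", "TF", "HP",
    "APOA1", "APOB", "FGA",
]

_CYTOKINES = [
    "IL8", "IL6", "TNFa", "IL10", "IL1b", "IL1ra", "IL2", "IL4", "IL5", "IL7",
    "IL12p40", "IL12p70", "IL13", "IL15", "IL17A", "IFNg", "IFNa2", "GCSF",
    "GMCSF", "MCP1", "MCP3", "MIP1a", "MIP1b", "IP10", "eotaxin", "EGF",
    "VEGF", "FGF2", "TNFb",
]  # 29

#: analytes that must survive QC because named downstream analyses use them
PROTECTED_ANALYTES = frozenset(
    _AMINO_ACIDS
    + ["propionate", "isobutyrate", "butyrate", "C0", "C2", "kynurenine", "IL8"]
)


def _pc_names(n: int) -> list[str]:
    names = []
    i = 0
    for total_c in range(30, 50, 2):
        for db in range(0, 7):
            for kind in ("aa", "ae"):
                names.append(f"PC {kind} C{total_c}:{db}")
                i += 1
                if i >= n:
                    return names
    while len(names) < n:  # pragma: no cover - panels larger than the grid
        names.append(f"PC aa C{50 + len(names)}:0")
    return names


def metabolite_panel(n: int = 206) -> pd.Series:
    """Analyte-id -> class for the first ``n`` metabolites of the panel.

    Ordered so small panels still contain the analytes named ratios use
    (amino acids, SCFAs, C0/C2, kynurenine/tryptophan).
    """
    ids, classes = [], []
    for group, cls in [
        (_AMINO_ACIDS, "amino acid"),
        (_ORGANIC_ACIDS, "organic acid"),
        (_BIOGENIC_AMINES, "biogenic amine"),
        (_ACYLCARNITINES, "acylcarnitine"),
        (_LYSOPCS, "lysoPC"),
        (_SMS, "SM"),
        (["hexoses"], "hexose"),
    ]:
        ids.extend(group)
        classes.extend([cls] * len(group))
    n_pc = max(0, n - len(ids))
    ids.extend(_pc_names(n_pc))
    classes.extend(["PC"] * n_pc)
    return pd.Series(classes[:n], index=ids[:n], name="class")


def protein_panel(n: int = 229) -> pd.Series:
    ids = list(_NAMED_PROTEINS[:n])
    ids += [f"PROT_{i:03d}" for i in range(1, n - len(ids) + 1)]
    return pd.Series("protein", index=ids[:n], name="class")


def cytokine_panel(n: int = 29) -> pd.Series:
    ids = list(_CYTOKINES[:n])
    ids += [f"CYT_{i:02d}" for i in range(1, n - len(ids) + 1)]
    return pd.Series("cytokine", index=ids[:n], name="class")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 92 matched pairs; 206
    assayed metabolites of which roughly 144 survive QC; 229 proteins;
    29 cytokines of which roughly 19 survive the detection rule.
    """

    n_pairs: int = 92
    n_hc: int = 0
    n_metabolites: int = 206
    n_proteins: int = 229
    n_cytokines: int = 29

    #: planted differential analytes per block (NS-vs-S mean shift)
    n_differential: dict[str, int] = field(
        default_factory=lambda: {"metabolite": 20, "protein": 15, "cytokine": 4}
    )
    delta_range: tuple[float, float] = (0.6, 1.2)

    #: within-class latent-factor correlation of log concentrations
    block_rho: float = 0.3
    #: SD of the pair-shared random effect, log10 units
    pair_sd: float = 0.15
    #: range of per-analyte residual SD, log10 units
    resid_sd_range: tuple[float, float] = (0.15, 0.35)

    #: left-censoring quantile for ordinarily well-detected metabolites
    lod_quantile: float = 0.02
    #: fraction of metabolites / cytokines censored heavily enough to
    #: fail the 80%-detection rule in both groups
    frac_low_detection: float = 0.06
    frac_low_detection_cytokine: float = 0.34
    low_detection_quantile: float = 0.35

    protein_dropout: float = 0.05
    frac_high_dropout: float = 0.08
    high_dropout_rate: float = 0.30

    n_batches: int | None = None  # None -> ceil(n_pairs / 5), TMT-plex style
    batch_shift_sd: float = 0.20

    #: planted group-specific correlation pairs (metabolite block)
    n_corr_shift_pairs: int = 8
    corr_r_s: float = 0.7
    corr_r_ns: float = 0.0

    #: cross-block correlation of IL8 with the pooled SCFAs (log scale)
    scfa_il8_r: float = 0.3

    #: QC replicates with exact per-analyte CV
    n_qc_replicates: int = 8
    qc_cv_fail_frac: float = 0.25
    qc_cv_pass_range: tuple[float, float] = (0.02, 0.25)
    qc_cv_fail_range: tuple[float, float] = (0.35, 0.60)

    #: severity gradient: multiplier on delta by time-to-death stratum
    severity_gradient: bool = True
    severity_factors: tuple[float, float, float] = (1.4, 1.0, 0.6)  # <=3, 4-7, >7 d

    #: clinical flag prevalence (NS, S) — Table-1-style danger signs
    flag_prevalence: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "diarrhea": (0.489, 0.326),
            "chest_indrawing": (0.359, 0.141),
            "severe_pneumonia": (0.359, 0.239),
            "fever": (0.337, 0.239),
            "vomiting": (0.283, 0.196),
        }
    )

    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("GeneratorConfig.seed must be set")
        if self.n_pairs < 3:
            raise ValidationError("n_pairs must be >= 3")
        for nm in ("n_metabolites", "n_proteins", "n_cytokines"):
            if getattr(self, nm) <= 0:
                raise ValidationError(f"{nm} must be positive")
        total = self.n_metabolites + self.n_proteins + self.n_cytokines
        n_diff = sum(self.n_differential.values())
        if not (0 <= n_diff <= total):
            raise ValidationError("n_differential outside [0, total analytes]")
        lo, hi = self.delta_range
        if not (-5 < lo <= hi < 5):
            raise ValidationError("delta range outside (-5, 5) is implausible")
        if self.n_qc_replicates < 2:
            raise ValidationError("need at least 2 QC replicates")

    def resolved_batches(self) -> int:
        if self.n_batches is not None:
            return self.n_batches
        return max(2, int(np.ceil(self.n_pairs / 5)))


# ---------------------------------------------------------------------------
# subject metadata


def _simulate_subjects(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_pairs
    rows = []
    n_batches = cfg.resolved_batches()
    sites = ["blantyre", "kilifi", "mombasa"]
    for i in range(n):
        pid = f"PAIR{i + 1:03d}"
        age = float(np.clip(np.exp(rng.normal(np.log(17.0), 0.6)), 6.0, 160.0))
        muac = float(np.clip(rng.normal(10.8, 1.2), 7.0, 14.5))
        hiv = rng.choice(["pos", "neg", "unknown"], p=[0.38, 0.49, 0.13])
        site = sites[int(rng.integers(len(sites)))]
        batch = f"B{(i % n_batches) + 1:02d}"
        # matched covariates: the control resembles its case
        for outcome in ("NS", "S"):
            if outcome == "NS":
                a, m, h = age, muac, hiv
                tte = int(min(1 + rng.geometric(0.25), 60))
            else:
                a = float(np.clip(age * np.exp(rng.normal(0, 0.10)), 6.0, 160.0))
                m = float(np.clip(muac + rng.normal(0, 0.3), 7.0, 14.5))
                h = hiv if rng.random() < 0.9 else rng.choice(["pos", "neg", "unknown"])
                tte = int(rng.integers(4, 15))
            row = {
                "outcome": outcome,
                "pair_id": pid,
                "age_months": round(a, 1),
                "muac_cm": round(m, 1),
                "hiv": h,
                "edema": bool(rng.random() < (0.315 if outcome == "NS" else 0.283)),
                "whz": round(float(rng.normal(-3.3, 1.3)), 2),
                "site": site,
                "batch": batch,
                "time_to_event_days": tte,
            }
            for flag, (p_ns, p_s) in cfg.flag_prevalence.items():
                row[f"flag_{flag}"] = bool(rng.random() < (p_ns if outcome == "NS" else p_s))
            rows.append(row)
    for j in range(cfg.n_hc):
        row = {
            "outcome": "HC",
            "pair_id": None,
            "age_months": round(float(np.clip(np.exp(rng.normal(np.log(20.0), 0.5)), 6.0, 160.0)), 1),
            "muac_cm": round(float(np.clip(rng.normal(14.5, 1.0), 12.0, 18.0)), 1),
            "hiv": "neg",
            "edema": False,
            "whz": round(float(rng.normal(-0.2, 1.0)), 2),
            "site": sites[int(rng.integers(len(sites)))],
            "batch": "B01",
            "time_to_event_days": 1,
        }
        for flag in cfg.flag_prevalence:
            row[f"flag_{flag}"] = False
        rows.append(row)
    subjects = pd.DataFrame(rows)
    subjects.index = pd.Index([f"SUBJ{i + 1:04d}" for i in range(len(subjects))], name="subject_id")
    return subjects


def _severity_factor(cfg: GeneratorConfig, tte: np.ndarray) -> np.ndarray:
    """Per-NS-subject multiplier on delta, normalised to unit mean under
    the configured geometric time-to-death distribution."""
    f_early, f_mid, f_late = cfg.severity_factors
    fac = np.where(tte <= 3, f_early, np.where(tte <= 7, f_mid, f_late))
    # P(tte<=3), P(4<=tte<=7), P(tte>7) under tte = 1 + Geometric(0.25)
    p = 0.25
    p_le3 = 1 - (1 - p) ** 2  # tte in {2,3}: support starts at 2
    p_47 = (1 - p) ** 2 - (1 - p) ** 6
    p_gt7 = (1 - p) ** 6
    mean = f_early * p_le3 + f_mid * p_47 + f_late * p_gt7
    return fac / mean


# ---------------------------------------------------------------------------
# analyte blocks


def _block_log_values(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    panel: pd.Series,
    subjects: pd.DataFrame,
    base_mean_loc: float,
    base_mean_sd: float,
    diff_ids: list[str],
    deltas: dict[str, float],
    corr_pairs: list[tuple[str, str, float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Return (log10 values, sigma_within per analyte)."""
    analytes = list(panel.index)
    p = len(analytes)
    n_sub = len(subjects)
    is_ns = (subjects["outcome"] == "NS").to_numpy()
    pair_ids = subjects["pair_id"].to_numpy(object)

    base = rng.normal(base_mean_loc, base_mean_sd, size=p)
    resid_sd = rng.uniform(*cfg.resid_sd_range, size=p)
    sigma_within = np.sqrt(cfg.pair_sd**2 + resid_sd**2)

    # class-structured residual correlation
    classes = panel.to_numpy()
    uniq = pd.unique(classes)
    factors = rng.normal(size=(n_sub, len(uniq)))
    cls_idx = np.searchsorted(uniq, classes, sorter=np.argsort(uniq))
    cls_idx = np.argsort(uniq)[cls_idx]
    eps = rng.normal(size=(n_sub, p))
    z = np.sqrt(cfg.block_rho) * factors[:, cls_idx] + np.sqrt(1 - cfg.block_rho) * eps

    # pair-shared random effect, independent across analytes
    u = np.zeros((n_sub, p))
    upairs = {pid: rng.normal(0.0, cfg.pair_sd, size=p) for pid in pd.unique(pair_ids) if pid is not None}
    for i, pid in enumerate(pair_ids):
        u[i] = upairs[pid] if pid is not None else rng.normal(0.0, cfg.pair_sd, size=p)

    log_vals = base[None, :] + u + z * resid_sd[None, :]

    # planted group-specific correlation: overwrite both analytes jointly,
    # no pair effect so the within-group correlation equals the target
    col = {a: j for j, a in enumerate(analytes)}
    for a, b, r_s, r_ns in corr_pairs:
        ja, jb = col[a], col[b]
        za = rng.normal(size=n_sub)
        zb_ind = rng.normal(size=n_sub)
        r = np.where(is_ns, r_ns, r_s)
        zb = r * za + np.sqrt(1 - r**2) * zb_ind
        log_vals[:, ja] = base[ja] + sigma_within[ja] * za
        log_vals[:, jb] = base[jb] + sigma_within[jb] * zb

    # planted NS-S shifts with the severity gradient
    if diff_ids:
        tte = subjects["time_to_event_days"].to_numpy(float)
        sev = np.ones(n_sub)
        if cfg.severity_gradient:
            sev[is_ns] = _severity_factor(cfg, tte[is_ns])
        for a in diff_ids:
            j = col[a]
            log_vals[is_ns, j] += deltas[a] * sigma_within[j] * sev[is_ns]
    return log_vals, sigma_within


def _choose(rng: np.random.Generator, pool: list[str], k: int) -> list[str]:
    k = min(k, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def generate_cohort(config: GeneratorConfig) -> CohortDataset:
    """Generate a matched NS/S cohort with recorded ground truth."""
    cfg = config
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_sub, rng_truth, rng_met, rng_prot, rng_cyt, rng_qc = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    subjects = _simulate_subjects(cfg, rng_sub)
    panels = {
        "metabolite": metabolite_panel(cfg.n_metabolites),
        "protein": protein_panel(cfg.n_proteins),
        "cytokine": cytokine_panel(cfg.n_cytokines),
    }

    # low-detection / high-dropout analytes never overlap the planted or
    # protected sets, so ground truth survives QC
    low_det: dict[str, list[str]] = {}
    met_pool = [a for a in panels["metabolite"].index if a not in PROTECTED_ANALYTES]
    low_det["metabolite"] = _choose(
        rng_truth, met_pool, int(round(cfg.frac_low_detection * cfg.n_metabolites))
    )
    cyt_pool = [a for a in panels["cytokine"].index if a not in PROTECTED_ANALYTES]
    low_det["cytokine"] = _choose(
        rng_truth, cyt_pool, int(round(cfg.frac_low_detection_cytokine * cfg.n_cytokines))
    )
    prot_pool = list(panels["protein"].index)
    high_drop = _choose(
        rng_truth, prot_pool, int(round(cfg.frac_high_dropout * cfg.n_proteins))
    )

    # QC CV-failing metabolites (chosen here; QC matrix realises them)
    met_cv_pool = [
        a for a in panels["metabolite"].index
        if a not in PROTECTED_ANALYTES and a not in low_det["metabolite"]
    ]
    cv_fail = _choose(
        rng_truth, met_cv_pool, int(round(cfg.qc_cv_fail_frac * cfg.n_metabolites))
    )

    # planted differential sets: organic acids / acylcarnitines up in NS,
    # lipids down, others random sign — mirroring the reported signature
    diff_ids: dict[str, list[str]] = {}
    deltas: dict[str, float] = {}
    removed = set(low_det["metabolite"]) | set(low_det["cytokine"]) | set(high_drop) | set(cv_fail)
    for block, rng_b in (("metabolite", rng_met), ("protein", rng_prot), ("cytokine", rng_cyt)):
        pool = [a for a in panels[block].index if a not in removed]
        if block == "cytokine":
            # IL8's variation is reserved for the planted SCFA coupling
            pool = [a for a in pool if a != "IL8"]
        chosen = _choose(rng_truth, pool, cfg.n_differential.get(block, 0))
        diff_ids[block] = chosen
        for a in chosen:
            mag = rng_truth.uniform(*cfg.delta_range)
            cls = panels[block].loc[a]
            if cls in ("organic acid", "acylcarnitine", "cytokine"):
                sign = 1.0
            elif cls in ("lysoPC", "SM", "PC"):
                sign = -1.0
            else:
                sign = 1.0 if rng_truth.random() < 0.5 else -1.0
            deltas[a] = sign * mag

    # correlation-shift pairs among non-differential amino acids
    aa_pool = [
        a for a in panels["metabolite"].index
        if panels["metabolite"].loc[a] == "amino acid" and a not in deltas
    ]
    corr_pairs: list[tuple[str, str, float, float]] = []
    k = min(cfg.n_corr_shift_pairs, len(aa_pool) // 2)
    picked = _choose(rng_truth, aa_pool, 2 * k)
    for i in range(k):
        corr_pairs.append((picked[2 * i], picked[2 * i + 1], cfg.corr_r_s, cfg.corr_r_ns))

    matrices: dict[str, AnalyteMatrix] = {}

    # --- metabolites ---
    panel = panels["metabolite"]
    log_vals, _ = _block_log_values(
        cfg, rng_met, panel, subjects, 1.0, 0.6, diff_ids["metabolite"], deltas, corr_pairs
    )
    vals = 10.0 ** log_vals
    lod = np.empty(len(panel))
    for j, a in enumerate(panel.index):
        q = cfg.low_detection_quantile if a in low_det["metabolite"] else cfg.lod_quantile
        lod[j] = np.quantile(vals[:, j], q)
    mask = vals < lod[None, :]
    matrices["metabolite"] = AnalyteMatrix(
        block="metabolite",
        values=pd.DataFrame(vals, index=subjects.index, columns=panel.index),
        mask=pd.DataFrame(mask, index=subjects.index, columns=panel.index),
        classes=panel.copy(),
        lod=pd.Series(lod, index=panel.index, name="lod"),
    )

    # --- proteins (batch shifts + MAR dropout) ---
    panel = panels["protein"]
    log_vals, _ = _block_log_values(
        cfg, rng_prot, panel, subjects, 4.0, 0.5, diff_ids["protein"], deltas, []
    )
    batches = subjects["batch"].to_numpy(object)
    for b in pd.unique(batches):
        shift = rng_prot.normal(0.0, cfg.batch_shift_sd, size=len(panel))
        log_vals[batches == b] += shift[None, :]
    vals = 10.0 ** log_vals
    rate = np.full(len(panel), cfg.protein_dropout)
    rate[[list(panel.index).index(a) for a in high_drop]] = cfg.high_dropout_rate
    mask = rng_prot.random(vals.shape) < rate[None, :]
    matrices["protein"] = AnalyteMatrix(
        block="protein",
        values=pd.DataFrame(vals, index=subjects.index, columns=panel.index),
        mask=pd.DataFrame(mask, index=subjects.index, columns=panel.index),
        classes=panel.copy(),
    )

    # --- cytokines (heavy censoring on the low-detection subset) ---
    panel = panels["cytokine"]
    log_vals, _ = _block_log_values(
        cfg, rng_cyt, panel, subjects, 1.0, 0.7, diff_ids["cytokine"], deltas, []
    )
    scfas = ["propionate", "isobutyrate", "butyrate"]
    if (
        cfg.scfa_il8_r != 0.0
        and "IL8" in panel.index
        and all(s in matrices["metabolite"].values.columns for s in scfas)
    ):
        # couple IL8 to the pooled SCFAs on the log scale, preserving
        # IL8's marginal mean and SD
        pooled = np.log10(matrices["metabolite"].values[scfas].sum(axis=1).to_numpy())
        z_scfa = (pooled - pooled.mean()) / pooled.std(ddof=1)
        j = list(panel.index).index("IL8")
        old = log_vals[:, j]
        z_old = (old - old.mean()) / old.std(ddof=1)
        r = cfg.scfa_il8_r
        log_vals[:, j] = old.mean() + old.std(ddof=1) * (r * z_scfa + np.sqrt(1 - r**2) * z_old)
    vals = 10.0 ** log_vals
    mask = np.zeros(vals.shape, dtype=bool)
    for a in low_det["cytokine"]:
        j = list(panel.index).index(a)
        thr = np.quantile(vals[:, j], cfg.low_detection_quantile)
        mask[:, j] = vals[:, j] < thr
    matrices["cytokine"] = AnalyteMatrix(
        block="cytokine",
        values=pd.DataFrame(vals, index=subjects.index, columns=panel.index),
        mask=pd.DataFrame(mask, index=subjects.index, columns=panel.index),
        classes=panel.copy(),
    )

    qc = _qc_matrix(cfg, rng_qc, panels["metabolite"], cv_fail)

    truth = SyntheticTruth(
        differential_set=[a for blk in ("metabolite", "protein", "cytokine") for a in diff_ids[blk]],
        effect_sizes=deltas,
        correlation_shift_pairs=corr_pairs,
        seed=cfg.seed,
    )
    return CohortDataset(subjects=subjects, matrices=matrices, qc_samples=qc, truth=truth)


# ---------------------------------------------------------------------------
# QC samples


def _qc_matrix(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    panel: pd.Series,
    cv_fail: list[str],
) -> pd.DataFrame:
    """Replicate x metabolite QC matrix with exact per-analyte sample CV.

    Replicates are ``mean * (1 + cv * z)`` with z standardised to sample
    mean 0 / SD 1, so sd/mean equals the drawn CV exactly; draws leaving
    a non-positive replicate are redrawn.
    """
    n_rep = cfg.n_qc_replicates
    if n_rep < 2:
        raise ValidationError("need at least 2 QC replicates")
    means = 10.0 ** rng.normal(1.0, 0.6, size=len(panel))
    out = np.empty((n_rep, len(panel)))
    for j, a in enumerate(panel.index):
        if a in cv_fail:
            cv = rng.uniform(*cfg.qc_cv_fail_range)
        else:
            cv = rng.uniform(*cfg.qc_cv_pass_range)
        for _ in range(100):
            z = rng.normal(size=n_rep)
            z = (z - z.mean()) / z.std(ddof=1)
            rep = means[j] * (1.0 + cv * z)
            if np.all(rep > 0):
                break
        else:  # pragma: no cover - cv ranges keep this unreachable
            rep = np.full(n_rep, means[j])
        out[:, j] = rep
    return pd.DataFrame(
        out, index=[f"QC{r + 1:02d}" for r in range(n_rep)], columns=panel.index
    )


def generate_qc_samples(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Standalone QC-sample matrix for the config's metabolite panel.

    Reproduces the QC matrix embedded in :func:`generate_cohort` when
    called with the same config (the failing subset is drawn from the
    same seed stream).
    """
    cfg = config if seed is None else dataclasses.replace(config, seed=seed)
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.spawn(6)
    rng_truth = np.random.default_rng(seeds[1])
    rng_qc = np.random.default_rng(seeds[5])
    panel = metabolite_panel(cfg.n_metabolites)
    # replay the truth stream up to the CV-fail draw (see generate_cohort)
    met_pool = [a for a in panel.index if a not in PROTECTED_ANALYTES]
    low_det = _choose(rng_truth, met_pool, int(round(cfg.frac_low_detection * cfg.n_metabolites)))
    cyt_pool = [a for a in cytokine_panel(cfg.n_cytokines).index if a not in PROTECTED_ANALYTES]
    _choose(rng_truth, cyt_pool, int(round(cfg.frac_low_detection_cytokine * cfg.n_cytokines)))
    _choose(rng_truth, list(protein_panel(cfg.n_proteins).index),
            int(round(cfg.frac_high_dropout * cfg.n_proteins)))
    met_cv_pool = [a for a in panel.index if a not in PROTECTED_ANALYTES and a not in low_det]
    cv_fail = _choose(rng_truth, met_cv_pool, int(round(cfg.qc_cv_fail_frac * cfg.n_metabolites)))
    return _qc_matrix(cfg, rng_qc, panel, cv_fail)


# ---------------------------------------------------------------------------
# unmatched pool for the matching module


def generate_unmatched_pool(
    n_cases: int,
    n_controls: int,
    seed: int,
    confounding: float = 1.0,
) -> pd.DataFrame:
    """Unmatched NS/S pool with covariate confounding for matching tests.

    Case status depends on age, MUAC and HIV with strength
    ``confounding`` (log-odds per SD), so pre-matching standardized mean
    differences are non-zero and nearest-neighbour matching has work to
    do.
    """
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    age = np.clip(np.exp(rng.normal(np.log(17.0), 0.6, size=n)), 6.0, 160.0)
    muac = np.clip(rng.normal(11.2, 1.3, size=n), 7.0, 15.0)
    hiv = rng.choice(["pos", "neg", "unknown"], size=n, p=[0.3, 0.58, 0.12])
    lin = (
        -confounding * (np.log(age) - np.log(17.0)) / 0.6
        - confounding * (muac - 11.2) / 1.3
        + confounding * (hiv == "pos")
    )
    score = 1.0 / (1.0 + np.exp(-(lin - np.median(lin))))
    # probabilistic case assignment: confounded but never separable
    take = rng.choice(n, size=n_cases, replace=False, p=score / score.sum())
    outcome = np.array(["S"] * n, dtype=object)
    outcome[take] = "NS"
    df = pd.DataFrame(
        {
            "outcome": outcome,
            "pair_id": None,
            "age_months": np.round(age, 1),
            "muac_cm": np.round(muac, 1),
            "hiv": hiv,
            "edema": rng.random(n) < 0.3,
            "whz": np.round(rng.normal(-3.3, 1.3, size=n), 2),
            "site": "kilifi",
            "batch": "B01",
            "time_to_event_days": rng.integers(1, 15, size=n),
        }
    )
    df.index = pd.Index([f"POOL{i + 1:04d}" for i in range(n)], name="subject_id")
    return df
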