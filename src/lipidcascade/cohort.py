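"""Synthetic cohorts with the statistical structure of a two-stage gastric-lesion
lipidomics study.

The generator emulates a screening cohort along the gastric precancerous cascade
(SG -> CAG -> IM -> LGIN -> HGIN -> invasive GC): a discovery and a validation
set with fixed stage composition, a prospectively followed subset with endpoint
histology, a multi-time-point sub-cohort, a lipid abundance matrix (mol/L) with
a small set of planted signal lipids inversely associated with both lesion
severity and future progression, pooled-plasma QC replicate rows, and a tissue
protein matrix linearly coupled to the signal lipids.

All planted structure is returned in ``SyntheticBundle.truth`` so downstream
recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Stage",
    "Subject",
    "GeneratorConfig",
    "SyntheticBundle",
    "generate_cohort",
    "generate_followup",
    "generate_proteins",
    "progression_outcome",
    "lesion_group",
    "write_bundle",
    "read_bundle",
    "config_to_dict",
]


class Stage(IntEnum):
    """Histology stage codes; the integer value is the severity score (1-6).

    ``GC`` is invasive carcinoma only. The analysis-level "GC group" is
    HGIN-or-worse, i.e. severity >= 5 (see :func:`lesion_group`).
    """

    SG = 1
    CAG = 2
    IM = 3
    LGIN = 4
    HGIN = 5
    GC = 6


def lesion_group(stage: Stage) -> str:
    """Collapse a stage into the three analysis groups: mild (SG/CAG),
    advanced (IM/LGIN), gc (HGIN or invasive GC)."""
    s = int(stage)
    if s <= 2:
        return "mild"
    if s <= 4:
        return "advanced"
    return "gc"


@dataclass
class Subject:
    id: str
    age: float
    sex: int  # 1 = male
    hp: int  # H. pylori seropositivity
    baseline_stage: Stage
    cohort: str  # "discovery" | "validation"
    visits: list[tuple[int, Stage]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.visits:
            self.visits = [(0, self.baseline_stage)]
        self._check_visits()

    def _check_visits(self) -> None:
        days = [d for d, _ in self.visits]
        if days != sorted(days) or days[0] != 0 or any(d < 0 for d in days):
            raise ValueError(f"subject {self.id}: visits must be sorted, start at day 0")
        if self.visits[0][1] != self.baseline_stage:
            raise ValueError(f"subject {self.id}: first visit must carry baseline stage")

    @property
    def endpoint(self) -> tuple[int, Stage]:
        return self.visits[-1]


def progression_outcome(subject: Subject) -> int:
    """-1 regression, 0 no change, +1 progression, comparing endpoint vs baseline severity."""
    end_sev = int(subject.endpoint[1])
    base_sev = int(subject.baseline_stage)
    return (end_sev > base_sev) - (end_sev < base_sev)


# Stage composition defaults: 200 discovery subjects (169 lesions + 22 HGIN +
# 9 invasive) and 200 validation subjects (152 lesions + 48 in the GC group).
# The split of the lesion counts across SG/CAG/IM/LGIN is a modelling choice.
_DISCOVERY_COUNTS = {Stage.SG: 30, Stage.CAG: 50, Stage.IM: 59, Stage.LGIN: 30,
                     Stage.HGIN: 22, Stage.GC: 9}
_VALIDATION_COUNTS = {Stage.SG: 27, Stage.CAG: 45, Stage.IM: 55, Stage.LGIN: 25,
                      Stage.HGIN: 28, Stage.GC: 20}

# The 11 planted signal lipids carry the names of real inverse markers of
# gastric lesion progression (3 free fatty acids, 8 phospholipids).
SIGNAL_LIPID_NAMES = [
    "PC38:6(20:4)", "PC38:5(20:4)", "PC34:3", "LysoPC18:3", "LysoPC20:4",
    "LPI18:0", "LPI20:4", "FFA20:4", "FFA18:3", "FFA18:0", "PA32:1",
]

# Class composition of the full targeted panel (counts for the default 624).
_NOISE_CLASS_COUNTS = [
    ("TAG", 199), ("PC", 85), ("PE", 63), ("PI", 27), ("SM", 27), ("PG", 27),
    ("LBPA", 27), ("DAG", 20), ("CE", 30), ("Cer", 25), ("FFA", 25),
    ("LysoPC", 20), ("LPE", 18), ("LPI", 10), ("PA", 10), ("PS", 12),
    ("GluCer", 12), ("SPH", 8), ("LPA", 8), ("GM3", 8), ("LacCer", 8),
    ("S1P", 4), ("LPS", 4),
]

_PROTEIN_NAMES = [
    "PTGS1", "ASAH1", "SLC27A3", "CES2", "ACY1", "PEBP1", "LYPLA2", "PITPNB",
    "PITPNA", "PAFAH1B2", "ATP8B1", "BDH1", "PLA2G4A", "LPCAT1", "PNPLA2",
    "ACSL1", "FASN", "SCD", "ELOVL5", "PLD1", "PITPNC1", "ACOT2", "CPT1A",
]


def _normalize_stage_keys(counts: dict) -> dict:
    out = {}
    for k, v in counts.items():
        st = Stage[k] if isinstance(k, str) else Stage(int(k))
        out[st] = int(v)
    return out


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``effect_size`` is the planted magnitude of the per-SD log-odds for the
    GC-group vs mild-lesion comparison (the planted OR per SD is exp(-effect_size)).
    ``progression_effect`` is the weight of the subject's latent progression
    risk inside the signal lipids; ``signal_correlation`` is the exchangeable
    pairwise correlation of the signal lipids on the log scale.
    """

    n_discovery: int = 200
    n_validation: int = 200
    n_prospective: int = 152
    n_subcohort: int = 76
    n_lipids: int = 624
    signal_lipids: int = 11
    effect_size: float = 1.3
    progression_effect: float = 0.55
    signal_correlation: float = 0.55
    noise_sd: float = 0.5
    age_effect: float = 0.1
    progression_base_rate: float = 0.25
    progression_severity_effect: float = 0.5  # log-odds per baseline stage
    regression_rate: float = 0.15
    risk_gamma: float = 1.0
    followup_median_days: float = 580.0
    followup_iqr_days: tuple[float, float] = (390.0, 806.0)
    n_clusters: int = 3
    cluster_sep: float = 3.0
    cluster_risk_corr: float = 0.5
    n_protein_subjects: int = 104
    n_proteins: int = 23
    protein_noise_sd: float = 2.5
    n_qc_discovery: int = 10
    n_qc_validation: int = 11
    qc_noise_sd: float = 0.02
    discovery_stage_counts: dict = field(default_factory=lambda: dict(_DISCOVERY_COUNTS))
    validation_stage_counts: dict = field(default_factory=lambda: dict(_VALIDATION_COUNTS))
    seed: int = 0

    def __post_init__(self) -> None:
        self.discovery_stage_counts = _normalize_stage_keys(self.discovery_stage_counts)
        self.validation_stage_counts = _normalize_stage_keys(self.validation_stage_counts)
        if isinstance(self.followup_iqr_days, list):
            self.followup_iqr_days = tuple(self.followup_iqr_days)
        for name in ("n_discovery", "n_validation", "n_prospective", "n_subcohort",
                     "n_lipids", "signal_lipids"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_prospective > self.n_validation:
            raise ValueError("n_prospective cannot exceed n_validation")
        if self.n_subcohort > self.n_prospective:
            raise ValueError("n_subcohort cannot exceed n_prospective")
        if not 0.0 <= self.signal_correlation < 1.0:
            raise ValueError("signal_correlation must lie in [0, 1)")
        if self.signal_lipids > self.n_lipids:
            raise ValueError("signal_lipids cannot exceed n_lipids")
        if sum(self.discovery_stage_counts.values()) != self.n_discovery:
            raise ValueError("discovery_stage_counts must sum to n_discovery")
        if sum(self.validation_stage_counts.values()) != self.n_validation:
            raise ValueError("validation_stage_counts must sum to n_validation")
        n_lesion_val = sum(v for k, v in self.validation_stage_counts.items()
                           if int(k) <= 4)
        if self.n_prospective > n_lesion_val:
            raise ValueError("n_prospective exceeds validation lesion count")


@dataclass
class SyntheticBundle:
    subjects: dict[str, list[Subject]]  # "discovery" / "validation"
    lipids: "LipidMatrix"  # raw mol/L, subjects x lipids
    qc_samples: pd.DataFrame  # QC replicate rows x lipids, raw mol/L
    proteins: pd.DataFrame  # protein-subset subjects x proteins
    link_table: pd.DataFrame  # columns: lipid_id, protein_id
    prospective_ids: list[str]
    subcohort_ids: list[str]
    truth: dict
    config: GeneratorConfig

    def all_subjects(self) -> list[Subject]:
        return self.subjects["discovery"] + self.subjects["validation"]

    def subject_table(self) -> pd.DataFrame:
        rows = []
        for s in self.all_subjects():
            rows.append({"id": s.id, "cohort": s.cohort, "age": s.age, "sex": s.sex,
                         "hp": s.hp, "baseline_stage": s.baseline_stage.name,
                         "severity": int(s.baseline_stage)})
        return pd.DataFrame(rows).set_index("id")


def _severity_z(config: GeneratorConfig) -> tuple[dict[int, float], float]:
    """Pooled-cohort severity standardization and the GC-vs-mild gap on the z scale."""
    counts = {}
    for table in (config.discovery_stage_counts, config.validation_stage_counts):
        for st, c in table.items():
            counts[int(st)] = counts.get(int(st), 0) + c
    sev = np.array(sorted(counts))
    w = np.array([counts[s] for s in sev], float)
    w /= w.sum()
    m = float(np.sum(w * sev))
    sd = float(np.sqrt(np.sum(w * (sev - m) ** 2)))
    z = {int(s): (s - m) / sd for s in sev}
    w_gc = np.array([counts.get(s, 0) for s in (5, 6)], float)
    w_mild = np.array([counts.get(s, 0) for s in (1, 2)], float)
    gap = 0.0
    if w_gc.sum() > 0 and w_mild.sum() > 0:
        z_gc = sum(counts.get(s, 0) * z.get(s, 0.0) for s in (5, 6)) / w_gc.sum()
        z_mild = sum(counts.get(s, 0) * z.get(s, 0.0) for s in (1, 2)) / w_mild.sum()
        gap = z_gc - z_mild
    return z, gap


def _lipid_ids(config: GeneratorConfig, rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    n_sig = config.signal_lipids
    sig_names = list(SIGNAL_LIPID_NAMES[:n_sig])
    while len(sig_names) < n_sig:
        sig_names.append(f"SIG{len(sig_names) + 1:02d}")
    n_noise = config.n_lipids - n_sig
    noise_names: list[str] = []
    classes = []
    for cls, cnt in _NOISE_CLASS_COUNTS:
        classes.extend([cls] * cnt)
    while len(classes) < n_noise:
        classes.append("TAG")
    classes = classes[:n_noise]
    counters: dict[str, int] = {}
    for cls in classes:
        counters[cls] = counters.get(cls, 0) + 1
        carbons = 30 + (counters[cls] * 7) % 30
        db = counters[cls] % 7
        name = f"{cls}{carbons}:{db}"
        if name in sig_names or name in noise_names:
            name = f"{name}#{counters[cls]}"
        noise_names.append(name)
    ids = sig_names + noise_names
    sig_idx = np.arange(n_sig)
    # shuffle columns so signal lipids are not trivially the first block
    perm = rng.permutation(config.n_lipids)
    ids = [ids[i] for i in perm]
    sig_idx = np.array([int(np.where(perm == j)[0][0]) for j in range(n_sig)])
    return ids, sig_idx


def generate_followup(
    subjects: Sequence[Subject],
    config: GeneratorConfig,
    latent_risk: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> list[Subject]:
    """Attach an endpoint visit to each subject.

    Follow-up time is log-normal, calibrated so the default median is 580 days
    with an interquartile width matching 390-806 days (median fixes mu; the
    IQR width fixes sigma). The endpoint stage follows a transition model in
    which the progression probability is logistic in the subject's latent risk
    and baseline stage: logit p = logit(progression_base_rate) + risk_gamma*u
    + progression_severity_effect*(stage-3). Non-progressors regress one stage
    with probability falling in the latent risk the same way.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    latent_risk = latent_risk or {}
    mu = math.log(config.followup_median_days)
    q1, q3 = config.followup_iqr_days
    iqr = q3 - q1
    # 2*median*sinh(z75*sigma) = IQR, z75 = Phi^-1(0.75)
    z75 = 0.6744897501960817
    sigma = math.asinh(iqr / (2.0 * config.followup_median_days)) / z75
    base = config.progression_base_rate
    for s in subjects:
        t = int(round(float(rng.lognormal(mu, sigma))))
        t = max(t, 30)
        u = float(latent_risk.get(s.id, 0.0))
        sev = int(s.baseline_stage)
        if base <= 0.0:
            p_prog = 0.0
        elif base >= 1.0:
            p_prog = 1.0
        else:
            # progression odds rise with latent risk and baseline stage
            p_prog = 1.0 / (1.0 + math.exp(-(
                math.log(base / (1 - base)) + config.risk_gamma * u
                + config.progression_severity_effect * (sev - 3))))
        if rng.random() < p_prog:
            step = 2 if rng.random() < 0.2 else 1
            end = min(6, sev + step)
        else:
            # regression odds fall with latent risk (proportional-odds style)
            rr = config.regression_rate
            if rr <= 0.0:
                p_reg = 0.0
            elif rr >= 1.0:
                p_reg = 1.0
            else:
                p_reg = 1.0 / (1.0 + math.exp(-(math.log(rr / (1 - rr))
                                                - config.risk_gamma * u)))
            if rng.random() < p_reg and sev > 1:
                end = sev - 1
            else:
                end = sev
        s.visits = [(0, s.baseline_stage), (t, Stage(end))]
    return list(subjects)


def generate_proteins(
    lipid_lognorm: pd.DataFrame,
    loadings: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator | None = None,
    protein_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Protein matrix linearly coupled to the (log-normalized) signal lipids.

    ``proteins = lipid_lognorm @ loadings + noise_sd * N(0,1)``.
    """
    loadings = np.asarray(loadings, float)
    if loadings.shape[0] != lipid_lognorm.shape[1]:
        raise ValueError(
            f"loadings rows ({loadings.shape[0]}) must match number of lipids "
            f"({lipid_lognorm.shape[1]})")
    if rng is None:
        rng = np.random.default_rng(0)
    vals = lipid_lognorm.to_numpy() @ loadings
    if noise_sd > 0:
        vals = vals + noise_sd * rng.standard_normal(vals.shape)
    if protein_names is None:
        protein_names = [f"P{j + 1:02d}" for j in range(loadings.shape[1])]
    return pd.DataFrame(vals, index=lipid_lognorm.index, columns=list(protein_names))


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticBundle:
    """Generate a full synthetic study bundle. Deterministic under ``config.seed``."""
    from .io_qc import LipidMatrix  # local import to avoid a cycle

    if config is None:
        config = GeneratorConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_subj, rng_lip, rng_fu, rng_prot, rng_misc = (
        np.random.default_rng(s) for s in ss.spawn(5))

    z_of, gap = _severity_z(config)
    e_sev = 0.0 if config.effect_size == 0 or gap <= 0 else config.effect_size / gap
    c = config.progression_effect
    rho = config.signal_correlation
    # the shared factor g and the latent risk u both load on the planted
    # cluster index (high-risk clusters have low lipid levels), so the common
    # variance of two signal lipids is e^2 + c^2 + w_g^2 + 2 c w_g kappa with
    # kappa = -cov(u, g) >= 0; solve the quadratic so that it equals rho.
    K = config.n_clusters
    var_idx = (K ** 2 - 1) / 12.0 if K > 1 else 0.0
    s_within = 1.0 / math.sqrt(1.0 + config.cluster_sep ** 2 * var_idx)
    kappa = s_within * config.cluster_sep * config.cluster_risk_corr * math.sqrt(var_idx)
    disc = (c * kappa) ** 2 + rho - e_sev ** 2 - c ** 2
    if disc < 0:
        raise ValueError(
            "signal_correlation too small for the requested effect sizes: "
            f"needs at least {e_sev ** 2 + c ** 2 - (c * kappa) ** 2:.3f}")
    w_g = -c * kappa + math.sqrt(disc)
    w_e = math.sqrt(1.0 - rho)

    # --- subjects -----------------------------------------------------------
    subjects: dict[str, list[Subject]] = {"discovery": [], "validation": []}
    for cohort, counts, prefix in (("discovery", config.discovery_stage_counts, "D"),
                                   ("validation", config.validation_stage_counts, "V")):
        stages: list[Stage] = []
        for st, cnt in counts.items():
            stages.extend([Stage(int(st))] * cnt)
        rng_subj.shuffle(stages)
        for i, st in enumerate(stages):
            sev = int(st)
            # age confounding: older subjects carry more advanced lesions
            age = float(np.clip(45.0 + 2.2 * sev + rng_subj.normal(0, 6.0), 40, 69))
            sex = int(rng_subj.random() < 0.55)
            p_hp = 1.0 / (1.0 + math.exp(-(0.6 + 0.15 * (sev - 3))))
            hp = int(rng_subj.random() < p_hp)
            subjects[cohort].append(Subject(
                id=f"{prefix}{i + 1:04d}", age=age, sex=sex, hp=hp,
                baseline_stage=st, cohort=cohort))

    all_subj = subjects["discovery"] + subjects["validation"]
    n = len(all_subj)
    ids = [s.id for s in all_subj]
    sev_z = np.array([z_of[int(s.baseline_stage)] for s in all_subj])
    age_z = np.array([(s.age - 55.0) / 7.0 for s in all_subj])

    # planted cluster structure enters through the shared lipid factor g
    # (negatively: higher cluster index, lower lipid level) and through the
    # latent progression risk u (positively), so clusters order by risk
    labels = rng_misc.integers(0, K, size=n)
    centered = labels - (K - 1) / 2.0
    g = s_within * (-config.cluster_sep * centered + rng_misc.standard_normal(n))
    lam = config.cluster_risk_corr
    if K > 1 and var_idx > 0:
        m_tilde = centered / math.sqrt(var_idx)
    else:
        m_tilde = np.zeros(n)
    u = lam * m_tilde + math.sqrt(max(0.0, 1.0 - lam ** 2)) * rng_misc.standard_normal(n)

    # --- lipid matrix -------------------------------------------------------
    lipid_ids, sig_idx = _lipid_ids(config, rng_lip)
    p = config.n_lipids
    n_sig = config.signal_lipids
    base_log = rng_lip.uniform(math.log(1e-8), math.log(1e-4), size=p)
    z_std = rng_lip.standard_normal((n, p))
    logdev = z_std.copy()
    sig_cols = sig_idx
    logdev[:, sig_cols] = (
        -e_sev * sev_z[:, None] - c * u[:, None] + w_g * g[:, None]
        + w_e * z_std[:, sig_cols])
    logdev += config.age_effect * age_z[:, None]
    raw = np.exp(base_log[None, :] + config.noise_sd * logdev)
    lipids = LipidMatrix(pd.DataFrame(raw, index=ids, columns=lipid_ids),
                         transform_state="raw")

    # --- QC replicate rows (pooled plasma, small technical noise) -----------
    pooled = np.exp(np.log(raw).mean(axis=0))
    qc_rows, qc_ids = [], []
    for stage_tag, n_qc in (("D", config.n_qc_discovery), ("V", config.n_qc_validation)):
        for r in range(n_qc):
            qc_ids.append(f"QC-{stage_tag}{r + 1:02d}")
            qc_rows.append(pooled * np.exp(
                config.qc_noise_sd * rng_lip.standard_normal(p)))
    qc = pd.DataFrame(qc_rows, index=qc_ids, columns=lipid_ids)

    # --- prospective follow-up ---------------------------------------------
    lesions_val = [s for s in subjects["validation"] if int(s.baseline_stage) <= 4]
    order = rng_fu.permutation(len(lesions_val))
    prospective = [lesions_val[i] for i in order[:config.n_prospective]]
    risk = {s.id: float(u[ids.index(s.id)]) for s in prospective}
    generate_followup(prospective, config, latent_risk=risk, rng=rng_fu)
    prospective_ids = [s.id for s in prospective]
    subcohort_ids = prospective_ids[:config.n_subcohort]
    for s in prospective:
        if s.id not in subcohort_ids:
            continue
        t_end, end_stage = s.visits[-1]
        t_mid = max(1, min(t_end - 1, int(round(t_end * rng_fu.uniform(0.4, 0.6)))))
        if end_stage != s.baseline_stage and rng_fu.random() < 0.5:
            mid_stage = end_stage
        else:
            mid_stage = s.baseline_stage
        s.visits = [s.visits[0], (t_mid, mid_stage), s.visits[-1]]

    # --- protein matrix coupled to signal lipids ----------------------------
    n_ps = min(config.n_protein_subjects, len(subjects["validation"]))
    pick = rng_prot.permutation(len(subjects["validation"]))[:n_ps]
    prot_subj = [subjects["validation"][i].id for i in sorted(pick)]
    sig_ids = [lipid_ids[j] for j in sig_idx]
    sub = lipids.values.loc[prot_subj, sig_ids]
    logs = np.log(sub.to_numpy())
    logs = (logs - logs.mean(0)) / logs.std(0)
    sub_ln = pd.DataFrame(logs, index=prot_subj, columns=sig_ids)
    prot_names = list(_PROTEIN_NAMES[:config.n_proteins])
    while len(prot_names) < config.n_proteins:
        prot_names.append(f"PROT{len(prot_names) + 1:02d}")
    loadings = np.zeros((n_sig, config.n_proteins))
    links = []
    for jp in range(config.n_proteins):
        k_links = int(rng_prot.integers(1, 4))
        linked = rng_prot.choice(n_sig, size=min(k_links, n_sig), replace=False)
        for jl in linked:
            loadings[jl, jp] = rng_prot.normal(0.0, 0.6)
            links.append({"lipid_id": sig_ids[jl], "protein_id": prot_names[jp]})
    proteins = generate_proteins(sub_ln, loadings, config.protein_noise_sd,
                                 rng=rng_prot, protein_names=prot_names)
    link_table = pd.DataFrame(links)

    truth = {
        "signal_indices": [int(j) for j in sig_idx],
        "signal_ids": sig_ids,
        "severity_slope": e_sev,
        "latent_risk": {sid: float(v) for sid, v in zip(ids, u)},
        "cluster_labels": {sid: int(l) + 1 for sid, l in zip(ids, labels)},
        "protein_loadings": loadings,
    }
    return SyntheticBundle(
        subjects=subjects, lipids=lipids, qc_samples=qc, proteins=proteins,
        link_table=link_table, prospective_ids=prospective_ids,
        subcohort_ids=subcohort_ids, truth=truth, config=config)


def config_to_dict(config: GeneratorConfig) -> dict:
    """YAML-safe plain-dict form of a GeneratorConfig (stage keys -> names)."""
    out = {}
    for k, v in asdict(config).items():
        if isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, dict):
            v = {(kk.name if isinstance(kk, Stage) else str(kk)): int(vv)
                 for kk, vv in v.items()}
        out[k] = v
    return out


def read_bundle(outdir: str | Path) -> SyntheticBundle:
    """Reconstruct a bundle from the CSVs + YAML sidecar written by write_bundle."""
    from .io_qc import LipidMatrix

    outdir = Path(outdir)
    with open(outdir / "bundle.yaml") as fh:
        sidecar = yaml.safe_load(fh)
    config = GeneratorConfig(**sidecar["config"])
    subj_df = pd.read_csv(outdir / "subjects.csv", index_col=0)
    visits_df = pd.read_csv(outdir / "visits.csv")
    visits: dict[str, list[tuple[int, Stage]]] = {}
    for _, row in visits_df.iterrows():
        visits.setdefault(row["id"], []).append((int(row["day"]), Stage[row["stage"]]))
    subjects: dict[str, list[Subject]] = {"discovery": [], "validation": []}
    for sid, row in subj_df.iterrows():
        subjects[row["cohort"]].append(Subject(
            id=sid, age=float(row["age"]), sex=int(row["sex"]), hp=int(row["hp"]),
            baseline_stage=Stage[row["baseline_stage"]], cohort=row["cohort"],
            visits=sorted(visits.get(sid, []), key=lambda v: v[0])))
    lipids = LipidMatrix(pd.read_csv(outdir / "lipids.csv", index_col=0),
                         transform_state="raw")
    truth = dict(sidecar["truth"])
    truth["protein_loadings"] = np.asarray(truth["protein_loadings"], float)
    return SyntheticBundle(
        subjects=subjects, lipids=lipids,
        qc_samples=pd.read_csv(outdir / "qc_samples.csv", index_col=0),
        proteins=pd.read_csv(outdir / "proteins.csv", index_col=0),
        link_table=pd.read_csv(outdir / "link_table.csv"),
        prospective_ids=list(sidecar["prospective_ids"]),
        subcohort_ids=list(sidecar["subcohort_ids"]),
        truth=truth, config=config)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as tidy CSVs plus a YAML sidecar with config and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["subjects"] = outdir / "subjects.csv"
    bundle.subject_table().to_csv(paths["subjects"])

    rows = []
    for s in bundle.all_subjects():
        for day, st in s.visits:
            rows.append({"id": s.id, "day": day, "stage": st.name,
                         "severity": int(st)})
    paths["visits"] = outdir / "visits.csv"
    pd.DataFrame(rows).to_csv(paths["visits"], index=False)

    paths["lipids"] = outdir / "lipids.csv"
    bundle.lipids.values.to_csv(paths["lipids"])
    paths["qc"] = outdir / "qc_samples.csv"
    bundle.qc_samples.to_csv(paths["qc"])
    paths["proteins"] = outdir / "proteins.csv"
    bundle.proteins.to_csv(paths["proteins"])
    paths["links"] = outdir / "link_table.csv"
    bundle.link_table.to_csv(paths["links"], index=False)

    sidecar = {
        "config": config_to_dict(bundle.config),
        "prospective_ids": bundle.prospective_ids,
        "subcohort_ids": bundle.subcohort_ids,
        "truth": {
            "signal_indices": bundle.truth["signal_indices"],
            "signal_ids": bundle.truth["signal_ids"],
            "severity_slope": float(bundle.truth["severity_slope"]),
            "latent_risk": bundle.truth["latent_risk"],
            "cluster_labels": bundle.truth["cluster_labels"],
            "protein_loadings": np.asarray(bundle.truth["protein_loadings"]).tolist(),
        },
    }
    paths["sidecar"] = outdir / "bundle.yaml"
    with open(paths["sidecar"], "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return paths
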