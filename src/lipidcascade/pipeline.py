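"""End-to-end orchestration of the analysis with serialized stage artifacts.

Stage order follows the study workflow: simulate -> QC/normalize ->
association cascade -> latent profiles -> clusters & trajectories ->
prediction -> lipid-protein integration. Every stage reads its inputs from
the artifacts the previous stages wrote, so any stage can be re-run from a
checkpoint; a manifest records seeds, configuration and content hashes of all
artifacts. Wall-clock timing goes to a JSON-lines log kept outside the
hashed artifact set so repeated runs of the same config + seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import CohortData, run_cascade
from .cluster_traj import (choose_k, cluster_progression_or, fit_trajectories,
                           pam_cluster, plot_trajectories, progression_flags)
from .cohort import (GeneratorConfig, Stage, SyntheticBundle, config_to_dict,
                     generate_cohort, lesion_group, progression_outcome,
                     read_bundle, write_bundle)
from .integration import cca_fit, hlt_per_cv, protein_gc_association, wilks_test
from .io_qc import log_normalize, qc_check
from .prediction import run_models
from .vaen import VAEConfig, vaen_run

__all__ = ["PipelineConfig", "StageError", "run_all", "make_report",
           "analysis_views", "STAGES"]

STAGES = ["simulate", "qc", "associate", "vaen", "cluster", "predict",
          "integrate"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    vae: VAEConfig = field(default_factory=VAEConfig)
    vip_threshold: float = 1.0
    p_threshold: float = 0.05
    q_threshold: float = 0.05
    k_range: tuple[int, int] = (2, 8)
    folds: int = 10
    n_permutations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_threshold", "q_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if isinstance(self.k_range, list):
            self.k_range = tuple(self.k_range)
        # one master seed, per-component streams derived deterministically
        self.generator.seed = self.seed
        self.vae.seed = self.seed + 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        vae = VAEConfig(**raw.pop("vae", {}))
        return cls(generator=gen, vae=vae, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = config_to_dict(self.generator)
        d["k_range"] = list(self.k_range)
        return d


def analysis_views(bundle: SyntheticBundle
                   ) -> tuple[CohortData, CohortData, CohortData]:
    """In-memory analysis-ready views (discovery, validation, prospective):
    per-cohort log-normalized lipids, covariates, lesion-group labels and the
    3-level progression outcome for the prospective subset."""
    table = bundle.subject_table()
    views = {}
    for cohort in ("discovery", "validation"):
        d = table[table.cohort == cohort]
        ln = log_normalize(bundle.lipids.subset(subject_ids=d.index))
        group = d["baseline_stage"].map(lambda s: lesion_group(Stage[s]))
        views[cohort] = CohortData(X=ln.values,
                                   covariates=d[["age", "sex", "hp"]],
                                   group=group)
    pro = bundle.prospective_ids
    subj = {s.id: s for s in bundle.subjects["validation"]}
    outcome = pd.Series({i: progression_outcome(subj[i]) for i in pro})
    prospective = CohortData(
        X=views["validation"].X.loc[pro],
        covariates=table.loc[pro][["age", "sex", "hp", "severity"]],
        outcome=outcome)
    return views["discovery"], views["validation"], prospective


def _log(outdir: Path, stage: str, seconds: float, seed: int) -> None:
    logdir = outdir / "logs"
    logdir.mkdir(parents=True, exist_ok=True)
    with open(logdir / "log.jsonl", "a") as fh:
        fh.write(json.dumps({"stage": stage, "seconds": round(seconds, 3),
                             "seed": seed}) + "\n")


# --------------------------------------------------------------------------
# stages (each reads prior artifacts from outdir and writes its own)
# --------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    bundle = generate_cohort(cfg.generator)
    write_bundle(bundle, outdir / "simulate")


def stage_qc(cfg: PipelineConfig, outdir: Path) -> None:
    bundle = read_bundle(outdir / "simulate")
    qcdir = outdir / "qc"
    qcdir.mkdir(parents=True, exist_ok=True)
    report = qc_check(bundle.qc_samples)
    report.to_json(qcdir / "qc_report.json")
    table = bundle.subject_table()
    for cohort in ("discovery", "validation"):
        ids = table.index[table["cohort"] == cohort]
        ln = log_normalize(bundle.lipids.subset(subject_ids=ids))
        out = ln.values.copy()
        out.index.name = "subject_id"
        out.to_csv(qcdir / f"lognorm_{cohort}.csv")


def _cohort_views(cfg: PipelineConfig, outdir: Path
                  ) -> tuple[CohortData, CohortData, CohortData, SyntheticBundle]:
    bundle = read_bundle(outdir / "simulate")
    table = bundle.subject_table()
    views = {}
    for cohort in ("discovery", "validation"):
        X = pd.read_csv(outdir / "qc" / f"lognorm_{cohort}.csv", index_col=0)
        sub = table.loc[X.index]
        group = sub["baseline_stage"].map(lambda s: lesion_group(Stage[s]))
        views[cohort] = CohortData(X=X, covariates=sub[["age", "sex", "hp"]],
                                   group=group)
    pro_ids = bundle.prospective_ids
    Xv = views["validation"].X
    pro_subjects = {s.id: s for s in bundle.subjects["validation"]}
    outcome = pd.Series({i: progression_outcome(pro_subjects[i]) for i in pro_ids})
    prospective = CohortData(
        X=Xv.loc[pro_ids],
        covariates=table.loc[pro_ids][["age", "sex", "hp", "severity"]],
        outcome=outcome)
    return views["discovery"], views["validation"], prospective, bundle


def stage_associate(cfg: PipelineConfig, outdir: Path) -> None:
    disc, val, pro, _ = _cohort_views(cfg, outdir)
    trace, records = run_cascade(disc, val, pro,
                                 vip_threshold=cfg.vip_threshold,
                                 p_threshold=cfg.p_threshold,
                                 q_threshold=cfg.q_threshold)
    adir = outdir / "associate"
    adir.mkdir(parents=True, exist_ok=True)
    records.to_csv(adir / "records.csv", index=False)
    with open(adir / "trace.json", "w") as fh:
        json.dump({"identified": trace.identified,
                   "vip_survivors": trace.vip_survivors,
                   "discovery_significant": trace.discovery_significant,
                   "validated": trace.validated,
                   "progression_associated": trace.progression_associated,
                   "surviving_lipids": records.attrs["surviving_lipids"]},
                  fh, indent=2, sort_keys=True)


def _surviving_lipids(outdir: Path) -> list[str]:
    with open(outdir / "associate" / "trace.json") as fh:
        return json.load(fh)["surviving_lipids"]


def stage_vaen(cfg: PipelineConfig, outdir: Path) -> None:
    _, val, _, bundle = _cohort_views(cfg, outdir)
    survivors = _surviving_lipids(outdir)
    vdir = outdir / "vaen"
    vdir.mkdir(parents=True, exist_ok=True)
    if not survivors:
        (vdir / "SKIPPED").write_text("zero validated lipids; latent stage skipped\n")
        return
    X = val.X[survivors]
    severity = bundle.subject_table().loc[X.index, "severity"].to_numpy(float)
    profiles = vaen_run(X, response=severity, targets=X, config=cfg.vae)
    out = profiles.latent.copy()
    out.index.name = "subject_id"
    out.to_csv(vdir / "latent.csv")
    profiles.diagnostics.to_csv(vdir / "diagnostics.csv", index=False)
    with open(vdir / "summary.json", "w") as fh:
        json.dump({"average_R2": profiles.average_R2,
                   "best_repeat": int(profiles.best_repeat),
                   "selected_dims": profiles.selected_dims},
                  fh, indent=2, sort_keys=True)


def stage_cluster(cfg: PipelineConfig, outdir: Path) -> None:
    bundle = read_bundle(outdir / "simulate")
    cdir = outdir / "cluster"
    cdir.mkdir(parents=True, exist_ok=True)
    if (outdir / "vaen" / "SKIPPED").exists():
        (cdir / "SKIPPED").write_text("no latent profiles\n")
        return
    latent = pd.read_csv(outdir / "vaen" / "latent.csv", index_col=0)
    pro_ids = [i for i in bundle.prospective_ids if i in latent.index]
    Z = latent.loc[pro_ids]
    lo, hi = cfg.k_range
    k, sil = choose_k(Z, range(lo, min(hi, len(Z) - 1) + 1))
    assign = pam_cluster(Z, k)
    pro_subjects = [s for s in bundle.subjects["validation"] if s.id in set(pro_ids)]
    flags = progression_flags(pro_subjects)
    # relabel clusters by ascending progression rate so cluster 1 is the
    # low-risk reference and the reported ORs read as risk increases
    rates = flags.groupby(assign.labels).mean().sort_values(kind="mergesort")
    remap = {old: new for new, old in enumerate(rates.index, start=1)}
    labels = assign.labels.map(remap)
    cov = bundle.subject_table().loc[pro_ids][["age", "sex", "hp", "severity"]]
    ors = cluster_progression_or(labels, flags, cov)
    traj = fit_trajectories(pro_subjects, labels)
    plot_trajectories(traj, cdir / "trajectories.svg")
    out = pd.DataFrame({"cluster": labels,
                        "silhouette": assign.silhouette})
    out.index.name = "subject_id"
    out.to_csv(cdir / "assignments.csv")
    traj.curves.to_csv(cdir / "trajectories.csv", index=False)
    ors.to_csv(cdir / "cluster_ors.csv", index=False)
    with open(cdir / "summary.json", "w") as fh:
        json.dump({"k": int(k),
                   "mean_silhouette": {int(kk): float(v) for kk, v in sil.items()},
                   "medoids": [str(m) for m in assign.medoids],
                   "anova_F": ors.attrs["anova_F"], "anova_p": ors.attrs["anova_p"],
                   "lr_chi2": ors.attrs["lr_chi2"], "lr_p": ors.attrs["lr_p"]},
                  fh, indent=2, sort_keys=True)


def stage_predict(cfg: PipelineConfig, outdir: Path) -> None:
    bundle = read_bundle(outdir / "simulate")
    pdir = outdir / "predict"
    pdir.mkdir(parents=True, exist_ok=True)
    table = bundle.subject_table()
    val_ids = table.index[table["cohort"] == "validation"]
    sev = table.loc[val_ids, "severity"]
    latent = None
    if (outdir / "vaen" / "latent.csv").exists():
        latent = pd.read_csv(outdir / "vaen" / "latent.csv", index_col=0)
    survivors = _surviving_lipids(outdir)
    Xv = pd.read_csv(outdir / "qc" / "lognorm_validation.csv", index_col=0)
    lipids = Xv[survivors] if survivors else None

    # Figure-5-style outcome set: multiclass histology; total GC; HGIN;
    # invasive GC; any progression; progression to IM or beyond.
    outcomes: dict[str, pd.Series] = {}
    grp = sev.map(lambda s: 0 if s <= 2 else (1 if s <= 4 else (2 if s == 5 else 3)))
    outcomes["histology_multiclass"] = grp
    outcomes["total_gc"] = (sev >= 5).astype(int)
    lesions = sev[sev <= 4].index
    outcomes["hgin"] = (sev[sev.index.isin(lesions) | (sev == 5)] == 5).astype(int)
    outcomes["invasive_gc"] = (sev[sev.index.isin(lesions) | (sev == 6)] == 6).astype(int)
    pro_subjects = {s.id: s for s in bundle.subjects["validation"]}
    pro_ids = bundle.prospective_ids
    prog = pd.Series({i: int(progression_outcome(pro_subjects[i]) > 0)
                      for i in pro_ids})
    outcomes["progression_any"] = prog
    endpoint = pd.Series({i: int(pro_subjects[i].endpoint[1]) for i in pro_ids})
    outcomes["progression_to_im_plus"] = ((prog == 1) & (endpoint >= 3)).astype(int)

    base = table[["age", "sex", "hp"]].copy()
    base_prog = table[["age", "sex", "hp", "severity"]].copy()
    comp_tables, dl_tables = [], []
    for name, y in outcomes.items():
        b = base_prog if name.startswith("progression") else base
        res = run_models(b, {name: y}, latent=latent, lipids=lipids,
                         folds=cfg.folds, seed=cfg.seed)
        comp_tables.append(res.table)
        if len(res.delong):
            dl_tables.append(res.delong)
    pd.concat(comp_tables, ignore_index=True).to_csv(pdir / "comparison.csv",
                                                     index=False)
    if dl_tables:
        pd.concat(dl_tables, ignore_index=True).to_csv(pdir / "delong.csv",
                                                       index=False)


def stage_integrate(cfg: PipelineConfig, outdir: Path) -> None:
    bundle = read_bundle(outdir / "simulate")
    idir = outdir / "integrate"
    idir.mkdir(parents=True, exist_ok=True)
    if bundle.proteins is None or bundle.proteins.empty:
        (idir / "SKIPPED").write_text("no protein matrix supplied\n")
        return
    survivors = _surviving_lipids(outdir)
    if not survivors:
        (idir / "SKIPPED").write_text("zero validated lipids\n")
        return
    prot_ids = list(bundle.proteins.index)
    Xv = pd.read_csv(outdir / "qc" / "lognorm_validation.csv", index_col=0)
    X = Xv.loc[prot_ids, survivors]
    Y = bundle.proteins
    res = cca_fit(X, Y)
    wt = wilks_test(res, X, Y, n_permutations=cfg.n_permutations, seed=cfg.seed)
    hlt = hlt_per_cv(res)
    table = bundle.subject_table()
    gc = (table.loc[prot_ids, "severity"] >= 5).astype(int)
    assoc = protein_gc_association(bundle.proteins, gc,
                                   table.loc[prot_ids][["age", "sex", "hp"]])
    res.x_weights.to_csv(idir / "lipid_weights.csv")
    res.y_weights.to_csv(idir / "protein_weights.csv")
    hlt.to_csv(idir / "hlt.csv", index=False)
    assoc.to_csv(idir / "protein_associations.csv", index=False)
    with open(idir / "cca.json", "w") as fh:
        json.dump({"canonical_correlations": [float(r) for r in res.correlations],
                   "wilks_lambda": res.wilks_lambda,
                   "wilks_perm_p": wt["perm_p"], "rao_F": wt["rao_F"],
                   "rao_p": wt["rao_p"], "ridge_used": res.ridge_used},
                  fh, indent=2, sort_keys=True)


_STAGE_FUNCS = {
    "simulate": stage_simulate, "qc": stage_qc, "associate": stage_associate,
    "vaen": stage_vaen, "cluster": stage_cluster, "predict": stage_predict,
    "integrate": stage_integrate,
}


def _hash_tree(outdir: Path) -> dict[str, str]:
    hashes = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_dir() or "logs" in p.parts or p.name in ("manifest.json", "report.md"):
            continue
        hashes[str(p.relative_to(outdir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return hashes


def run_all(cfg: PipelineConfig, outdir: str | Path,
            stages: list[str] | None = None) -> dict:
    """Execute the pipeline stages in workflow order, writing artifacts,
    a manifest with versions/seeds/hashes, and a human-readable report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in stages or STAGES:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](cfg, outdir)
        except Exception as e:  # halt with a labelled error
            raise StageError(stage, e) from e
        _log(outdir, stage, time.perf_counter() - t0, cfg.seed)
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": stages or STAGES,
        "artifact_sha256": _hash_tree(outdir),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report = make_report(outdir)
    (outdir / "report.md").write_text(report)
    return manifest


def make_report(outdir: str | Path) -> str:
    """Assemble a markdown summary from whatever stage artifacts exist."""
    outdir = Path(outdir)
    lines = ["# Lipidomics cascade report", ""]
    man = outdir / "manifest.json"
    if man.exists():
        cfg = json.loads(man.read_text())
        lines += [f"Package version {cfg['package_version']}, master seed "
                  f"{cfg['seed']}.", ""]
        lines += ["```yaml", yaml.safe_dump(cfg["config"], sort_keys=True).rstrip(),
                  "```", ""]
    qc = outdir / "qc" / "qc_report.json"
    if qc.exists():
        q = json.loads(qc.read_text())
        lines += ["## QC", f"Pairwise QC rank correlations {q['min_r']:.3f}-"
                  f"{q['max_r']:.3f}; drift {q['drift']:.1%}; "
                  f"{'PASS' if q['passed'] else 'FAIL'}.", ""]
    tr = outdir / "associate" / "trace.json"
    if tr.exists():
        t = json.loads(tr.read_text())
        lines += ["## Lipid filter cascade",
                  f"identified {t['identified']} -> VIP>1 {t['vip_survivors']} -> "
                  f"discovery-significant {t['discovery_significant']} -> "
                  f"validated {t['validated']} -> progression-associated "
                  f"{t['progression_associated']}", ""]
        if t["progression_associated"] == 0:
            lines += ["Zero validated lipids; downstream latent/cluster/"
                      "integration sections skipped.", ""]
        else:
            rec = pd.read_csv(outdir / "associate" / "records.csv")
            keep = rec[rec["lipid_id"].isin(t["surviving_lipids"])]
            cols = [c for c in ("lipid_id", "comparison", "stage", "VIP", "OR",
                                "p", "fdr_q") if c in keep.columns]
            lines += ["### Association table (surviving lipids)", "",
                      keep[cols].round(4).to_string(index=False), ""]
    vs = outdir / "vaen" / "summary.json"
    if vs.exists():
        v = json.loads(vs.read_text())
        lines += ["## Latent profiles",
                  f"Best repeat {v['best_repeat']} with average R2 = "
                  f"{v['average_R2']:.3f}; dims {v['selected_dims']}.", ""]
    cs = outdir / "cluster" / "summary.json"
    if cs.exists():
        c = json.loads(cs.read_text())
        lines += ["## Clusters", f"k = {c['k']} by silhouette; progression "
                  f"heterogeneity LR chi2 = {c['lr_chi2']}, "
                  f"ANOVA F = {c['anova_F']:.2f} (p = {c['anova_p']:.2e})", ""]
        ors = pd.read_csv(outdir / "cluster" / "cluster_ors.csv")
        lines += [ors.round(3).to_string(index=False), ""]
    pc = outdir / "predict" / "comparison.csv"
    if pc.exists():
        lines += ["## Prediction models", "",
                  pd.read_csv(pc).round(3).to_string(index=False), ""]
        dl = outdir / "predict" / "delong.csv"
        if dl.exists():
            lines += [pd.read_csv(dl).round(4).to_string(index=False), ""]
    ic = outdir / "integrate" / "cca.json"
    if ic.exists():
        i = json.loads(ic.read_text())
        rs = ", ".join(f"{r:.3f}" for r in i["canonical_correlations"])
        lines += ["## Lipid-protein integration",
                  f"Canonical correlations: {rs}; Wilks lambda = "
                  f"{i['wilks_lambda']:.4f} (permutation p = {i['wilks_perm_p']:.4g}, "
                  f"Rao F p = {i['rao_p']:.4g})", ""]
    skipped = [s.parent.name for s in outdir.rglob("SKIPPED")]
    if skipped:
        lines += ["## Skipped stages", ", ".join(sorted(skipped)), ""]
    return "\n".join(lines)
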