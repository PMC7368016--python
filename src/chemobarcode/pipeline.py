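"""End-to-end per-patient and cohort pipeline.

Stages, in the order the analysis requires them: Dirichlet-process
clustering of mutations in multi-sample CCF space -> cluster filtering
(">50 mutations" rule, optional donor-SNP exclusion) -> pigeonhole tree
construction -> per-cluster signature fitting with bootstrap CIs ->
seeding classification from the chemotherapy barcode -> trajectory-
corrected SBS1 branch:trunk ratio.  Cohort runs add the Wilcoxon
comparison of ratios between diagnosis and relapse groups.

Every stage writes its outputs under ``outdir/<patient>/`` and a run
manifest records the seed and parameters, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalogs import (
    MutationRecord,
    SignatureReference,
    build_catalog,
    read_signature_reference,
    sample_names,
)
from .clustering import DPConfig, DirichletProcessModel, filter_clusters
from .fitting import (
    SignatureFitResults,
    StrandBiasResult,
    bootstrap_ci,
    strand_bias_for_signature,
)
from .phylogeny import PhyloTree, build_tree, enumerate_trajectories
from .seeding import (
    SeedingCall,
    classify_seeding,
    compare_groups,
    sbs1_counts_from_fits,
    sbs1_ratio,
)
from .simulate import synthetic_signature_reference

logger = logging.getLogger("chemobarcode")


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage for a named patient."""

    def __init__(self, stage: str, patient: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for patient {patient!r}: {cause}")
        self.stage = stage
        self.patient = patient
        self.cause = cause


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline in one place."""

    purity: float = 0.9
    dp: DPConfig = field(default_factory=DPConfig)
    clonal_ccf_threshold: float = 0.85
    tree_tolerance: float = 0.05
    elimination_threshold: float = 0.01
    n_boot: int = 1000
    detection_threshold: float = 0.05
    chemo_signatures: tuple[str, ...] = ("SBS-MM1", "SBS35")
    allo_mode: bool = False
    rng_seed: int = 0
    signature_reference: str | None = None  # path; default bundled synthetic

    def reference(self) -> SignatureReference:
        if self.signature_reference is None:
            return synthetic_signature_reference()
        return read_signature_reference(self.signature_reference)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chemo_signatures"] = list(self.chemo_signatures)
        return d

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "dp" in d:
            d["dp"] = DPConfig(**d["dp"])
        if "chemo_signatures" in d:
            d["chemo_signatures"] = tuple(d["chemo_signatures"])
        return cls(**d)


@dataclass
class PatientReport:
    """Everything the pipeline concluded about one patient."""

    patient: str
    n_mutations: int
    n_clusters_raw: int
    n_clusters_kept: int
    tree: PhyloTree
    node_exposures: dict[str, SignatureFitResults]
    sample_exposures: SignatureFitResults
    strand_bias: dict[str, StrandBiasResult]
    seeding: SeedingCall
    ratio: float | None
    trunk_sbs1: float | None
    n_trajectories: int

    def to_dict(self) -> dict:
        return {
            "patient": self.patient,
            "n_mutations": self.n_mutations,
            "n_clusters_raw": self.n_clusters_raw,
            "n_clusters_kept": self.n_clusters_kept,
            "scenario": self.seeding.scenario,
            "detection_threshold": self.seeding.detection_threshold,
            "evidence": self.seeding.evidence.to_dict(orient="records"),
            "sample_exposures": self.sample_exposures.to_frame().to_dict(orient="records"),
            "strand_bias": {
                sig: {
                    "transcribed": sb.transcribed_count,
                    "untranscribed": sb.untranscribed_count,
                    "ratio": sb.ratio,
                    "p_value": sb.p_value,
                    "significant": sb.significant,
                }
                for sig, sb in sorted(self.strand_bias.items())
            },
            "sbs1_ratio": self.ratio,
            "trunk_sbs1": self.trunk_sbs1,
            "n_trajectories": self.n_trajectories,
            "trunk_fraction": self.tree.trunk_fraction(),
            "tree": self.tree.to_dict(),
        }


def _stage(stage: str, patient: str):
    import time

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("patient=%s stage=%s start", patient, stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(stage, patient, exc) from exc
            logger.info(
                "patient=%s stage=%s done wall=%.2fs",
                patient, stage, time.perf_counter() - self.t0,
            )
            return False

    return _Ctx()


def run_patient(
    config: PipelineConfig,
    mutations: list[MutationRecord],
    patient: str = "patient",
    seed: int | None = None,
    outdir: str | Path | None = None,
    reference: SignatureReference | None = None,
) -> PatientReport:
    """Run the full per-patient inference chain.

    ``seed`` overrides the configured seed (the cohort runner derives
    per-patient seeds from the master seed).  If ``outdir`` is given all
    stage outputs and a run manifest are written beneath it.
    """
    ref = reference if reference is not None else config.reference()
    seed = config.rng_seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples = sample_names(mutations)
    purity = {s: config.purity for s in samples}

    with _stage("cluster", patient):
        model = DirichletProcessModel.from_mutations(mutations, purity, config.dp)
        dp_results = model.fit(seed=int(rng.integers(0, 2**31 - 1)))

    with _stage("filter", patient):
        kept = filter_clusters(dp_results.clusters, config.dp, allo_mode=config.allo_mode)

    with _stage("tree", patient):
        tree = build_tree(
            kept,
            clonal_ccf_threshold=config.clonal_ccf_threshold,
            tolerance=config.tree_tolerance,
        )
        trajectories = enumerate_trajectories(tree)

    with _stage("fit", patient):
        node_exposures: dict[str, SignatureFitResults] = {}
        for c in tree.nodes:
            catalog = build_catalog([mutations[i] for i in c.members])
            node_exposures[c.id] = bootstrap_ci(
                catalog,
                ref,
                n_boot=config.n_boot,
                seed=int(rng.integers(0, 2**31 - 1)),
                elimination_threshold=config.elimination_threshold,
            )
        sample_exposures = bootstrap_ci(
            build_catalog(mutations),
            ref,
            n_boot=config.n_boot,
            seed=int(rng.integers(0, 2**31 - 1)),
            elimination_threshold=config.elimination_threshold,
        )
        strand_bias: dict[str, StrandBiasResult] = {}
        for sig in config.chemo_signatures:
            if sig in sample_exposures.retained:
                try:
                    strand_bias[sig] = strand_bias_for_signature(
                        mutations, sample_exposures, sig
                    )
                except ValueError:
                    pass  # no stranded mutations attributed to this signature

    with _stage("classify", patient):
        seeding = classify_seeding(
            tree,
            node_exposures,
            chemo_signatures=config.chemo_signatures,
            detection_threshold=config.detection_threshold,
            min_node_size=config.dp.min_cluster_size,
            patient=patient,
        )

    with _stage("ratio", patient):
        counts = sbs1_counts_from_fits(tree, node_exposures)
        try:
            rr = sbs1_ratio(tree, counts, patient=patient)
            ratio, trunk_sbs1 = rr.ratio, rr.trunk_sbs1
        except ValueError:
            ratio, trunk_sbs1 = None, None

    report = PatientReport(
        patient=patient,
        n_mutations=len(mutations),
        n_clusters_raw=len(dp_results.clusters),
        n_clusters_kept=len(kept),
        tree=tree,
        node_exposures=node_exposures,
        sample_exposures=sample_exposures,
        strand_bias=strand_bias,
        seeding=seeding,
        ratio=ratio,
        trunk_sbs1=trunk_sbs1,
        n_trajectories=trajectories.count,
    )
    if outdir is not None:
        _write_patient_outputs(config, report, dp_results, Path(outdir), seed)
    return report


def _write_patient_outputs(config, report, dp_results, outdir: Path, seed: int) -> None:
    pdir = outdir / report.patient
    pdir.mkdir(parents=True, exist_ok=True)
    dp_results.to_frame().to_csv(pdir / "clusters.tsv", sep="\t", index=False)
    (pdir / "tree.json").write_text(report.tree.to_json() + "\n")
    (pdir / "tree.nwk").write_text(report.tree.to_newick() + "\n")
    exposures = pd.concat(
        [f.to_frame().assign(node=node) for node, f in sorted(report.node_exposures.items())],
        ignore_index=True,
    )
    exposures.to_csv(pdir / "exposures.tsv", sep="\t", index=False)
    (pdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    manifest = {
        "patient": report.patient,
        "seed": seed,
        "version": __version__,
        "parameters": config.to_dict(),
        "outputs": sorted(p.name for p in pdir.iterdir()) + ["manifest.json"],
    }
    (pdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def run_cohort(
    config: PipelineConfig,
    patients: list[tuple[str, str, list[MutationRecord]]],
    outdir: str | Path | None = None,
    reference: SignatureReference | None = None,
) -> dict:
    """Run all patients and compare diagnosis vs relapse SBS1 ratios.

    ``patients`` is a list of (patient_id, group, mutations) with group
    in {diagnosis, relapse}.  Per-patient seeds are spawned from the
    configured master seed in list order.
    """
    ids = [p[0] for p in patients]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient id(s) {dupes}")
    ref = reference if reference is not None else config.reference()
    seeds = np.random.SeedSequence(config.rng_seed).spawn(len(patients))
    reports: list[tuple[str, PatientReport]] = []
    rows = []
    for (pid, group, muts), ss in zip(patients, seeds):
        seed = int(np.random.default_rng(ss).integers(0, 2**31 - 1))
        report = run_patient(
            config, muts, patient=pid, seed=seed, outdir=outdir, reference=ref
        )
        reports.append((group, report))
        rows.append(
            {
                "patient": pid,
                "group": group,
                "scenario": report.seeding.scenario,
                "sbs1_ratio": report.ratio,
                "n_trajectories": report.n_trajectories,
            }
        )
    table = pd.DataFrame(rows)

    comparison = None
    diag = [r["sbs1_ratio"] for r in rows if r["group"] == "diagnosis" and r["sbs1_ratio"] is not None]
    rel = [r["sbs1_ratio"] for r in rows if r["group"] == "relapse" and r["sbs1_ratio"] is not None]
    if diag and rel:
        gc = compare_groups(diag, rel)
        comparison = {
            "median_diagnosis": gc.median_diagnosis,
            "median_relapse": gc.median_relapse,
            "p_value": gc.p_value,
            "diagnosis_higher": gc.diagnosis_higher,
        }
    else:
        warnings.warn("only one group present; skipping group comparison")

    result = {
        "patients": rows,
        "comparison": comparison,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
        (outdir / "comparison.json").write_text(
            json.dumps(result, indent=2, sort_keys=True, default=float) + "\n"
        )
    return result
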