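"""Seeding classification from chemotherapy barcodes and the SBS1 ratio.

Chemotherapy-induced mutations mark every exposed cell with a private
set of mutations; that set becomes visible to bulk sequencing only when
a single exposed cell expands clonally.  Where the chemotherapy
signature sits on the patient's clone tree therefore dates the seeding
of anatomic sites relative to exposure: in the trunk, a single
surviving cell re-seeded every site after treatment
(``single_cell_seeding``); in parallel branches but not the trunk, the
site-specific clones pre-existed the exposure (``preexisting_clones``);
nowhere, no exposed clone expanded (``no_chemo_signature``); trunk plus
additional private branch barcodes indicate sequential exposures
(``mixed``).

The pace of divergence is measured with the clock-like signature SBS1:
for each evolutionary trajectory, the SBS1 mutations accumulated on its
non-trunk nodes are compared with the trunk's, and the patient's
branch:trunk SBS1 ratio is the mean of the per-trajectory ratios.
Averaging over trajectories is the correction that avoids pooling
mutations acquired in parallel lineages.  Low ratios mean late
divergence (fast seeding); group differences are tested with the
two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import SignatureFitResults
from .phylogeny import PhyloTree, enumerate_trajectories

SCENARIO_LABELS = (
    "single_cell_seeding",
    "preexisting_clones",
    "no_chemo_signature",
    "mixed",
)


@dataclass
class SeedingCall:
    """Per-patient seeding classification with its node-level evidence."""

    patient: str
    scenario: str
    evidence: pd.DataFrame
    detection_threshold: float

    def detected_nodes(self) -> list[str]:
        return sorted(self.evidence.loc[self.evidence["detected"], "node"].unique())


def _is_detected(
    fit: SignatureFitResults, signature: str, threshold: float
) -> tuple[bool, float, float]:
    if signature not in fit.signatures:
        return False, 0.0, 0.0
    j = fit.signatures.index(signature)
    prop = float(fit.proportions[j])
    if fit.ci_low is None:
        raise ValueError("exposure fit lacks bootstrap confidence intervals")
    lo = float(fit.ci_low[j])
    return (prop >= threshold and lo > 0.0), prop, lo


def classify_seeding(
    tree: PhyloTree,
    node_exposures: dict[str, SignatureFitResults],
    chemo_signatures: tuple[str, ...] = ("SBS-MM1", "SBS35"),
    detection_threshold: float = 0.05,
    min_node_size: int = 50,
    patient: str = "patient",
) -> SeedingCall:
    """Classify the disease-seeding scenario of one patient.

    A chemotherapy signature is "detected" in a node when its fitted
    exposure proportion is at least ``detection_threshold`` and the
    bootstrap lower confidence bound is above zero.  Exposure fits must
    be supplied for the trunk and every branch node with more than
    ``min_node_size`` mutations.
    """
    qualifying = [tree.trunk] + [
        c.id for c in tree.branch_nodes if c.size > min_node_size
    ]
    missing = [n for n in qualifying if n not in node_exposures]
    if missing:
        raise ValueError(f"missing exposures for node(s) {missing}")

    rows = []
    for node_id in qualifying:
        fit = node_exposures[node_id]
        for sig in chemo_signatures:
            det, prop, lo = _is_detected(fit, sig, detection_threshold)
            rows.append(
                {
                    "node": node_id,
                    "is_trunk": node_id == tree.trunk,
                    "signature": sig,
                    "proportion": prop,
                    "ci_low": lo,
                    "detected": det,
                }
            )
    evidence = pd.DataFrame(rows)

    trunk_hit = bool(evidence.loc[evidence["is_trunk"], "detected"].any())
    branch_hits = sorted(
        evidence.loc[~evidence["is_trunk"] & evidence["detected"], "node"].unique()
    )
    if trunk_hit and branch_hits:
        scenario = "mixed"
    elif trunk_hit:
        scenario = "single_cell_seeding"
    elif branch_hits:
        scenario = "preexisting_clones"
    else:
        scenario = "no_chemo_signature"
    return SeedingCall(
        patient=patient,
        scenario=scenario,
        evidence=evidence,
        detection_threshold=detection_threshold,
    )


@dataclass
class SBS1RatioResult:
    """Trajectory-corrected branch:trunk SBS1 ratio for one patient."""

    patient: str
    trunk_sbs1: float
    per_trajectory_branch_sbs1: list[float]
    ratio: float

    @property
    def n_trajectories(self) -> int:
        return len(self.per_trajectory_branch_sbs1)


def sbs1_ratio(
    tree: PhyloTree,
    sbs1_counts: dict[str, float],
    patient: str = "patient",
) -> SBS1RatioResult:
    """Mean over trajectories of (branch SBS1 sum / trunk SBS1).

    For each trajectory the SBS1 counts of its non-trunk nodes are
    summed; parallel trajectories are never pooled together.  The
    trunk's SBS1 count must be positive.
    """
    trunk = float(sbs1_counts.get(tree.trunk, 0.0))
    if trunk <= 0:
        raise ValueError("trunk SBS1 count must be positive (ratio undefined)")
    trajectories = enumerate_trajectories(tree)
    per_traj = []
    for path in trajectories.paths:
        branch_sum = sum(float(sbs1_counts.get(n, 0.0)) for n in path if n != tree.trunk)
        per_traj.append(branch_sum)
    ratio = float(np.mean([b / trunk for b in per_traj]))
    return SBS1RatioResult(
        patient=patient,
        trunk_sbs1=trunk,
        per_trajectory_branch_sbs1=per_traj,
        ratio=ratio,
    )


def sbs1_counts_from_fits(
    tree: PhyloTree,
    node_exposures: dict[str, SignatureFitResults],
    signature: str = "SBS1",
) -> dict[str, float]:
    """Per-node SBS1 mutation counts from fitted exposures.

    Counts are exposure proportion times cluster size (rather than raw
    channel counts, whose C>T-at-CpG channels overlap other processes).
    """
    counts = {}
    for c in tree.nodes:
        fit = node_exposures.get(c.id)
        if fit is None:
            continue
        counts[c.id] = fit.proportion(signature) * c.size if signature in fit.signatures else 0.0
    return counts


@dataclass
class GroupComparison:
    """Wilcoxon rank-sum comparison of per-patient SBS1 ratios."""

    median_diagnosis: float
    median_relapse: float
    p_value: float
    diagnosis_higher: bool
    statistic: float

    def summary(self) -> str:
        direction = (
            "diagnosis > relapse" if self.diagnosis_higher else "diagnosis <= relapse"
        )
        return (
            "SBS1 branch:trunk ratio comparison (Wilcoxon rank-sum, two-sided)\n"
            f"  median diagnosis: {self.median_diagnosis:.3f}\n"
            f"  median relapse:   {self.median_relapse:.3f}\n"
            f"  p-value: {self.p_value:.3g}   direction: {direction}"
        )


def compare_groups(
    ratios_diagnosis: list[float], ratios_relapse: list[float]
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test between patient groups."""
    if not ratios_diagnosis or not ratios_relapse:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(
        ratios_diagnosis, ratios_relapse, alternative="two-sided"
    )
    med_d = float(np.median(ratios_diagnosis))
    med_r = float(np.median(ratios_relapse))
    return GroupComparison(
        median_diagnosis=med_d,
        median_relapse=med_r,
        p_value=float(res.pvalue),
        diagnosis_higher=med_d > med_r,
        statistic=float(res.statistic),
    )
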