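"""Synthetic multi-site cohorts with known phylogenies and signature mixtures.

The generator emulates multi-region tumor sequencing of one patient:
a clone tree is specified as clusters with per-sample CCFs (consistent
with the pigeonhole principle by construction), each cluster draws its
mutations' trinucleotide channels from a cluster-specific mixture of
signature profiles, and read counts per sample follow the standard
diploid mapping VAF = purity * CCF / 2 with Poisson depth and binomial
sampling noise.  Chemotherapy-signature mutations receive transcribed /
untranscribed strand labels with configurable odds, emulating the
transcriptional strand bias of adduct-forming agents; a configurable
fraction of mutations is intergenic and unstranded.

Scenarios place the chemotherapy barcode on the tree: ``trunk_chemo``
plants it in the trunk (single surviving cell re-seeded all sites),
``branch_chemo`` in two disjoint branches (sites pre-existed exposure),
``no_chemo`` nowhere.  Cohorts of diagnosis-like (early divergence,
large branch SBS1 load) and relapse-like (late divergence, small branch
SBS1 load) patients support the branch:trunk SBS1 ratio comparison.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .catalogs import (
    CHANNELS_96,
    COMPLEMENT,
    MutationRecord,
    SignatureReference,
    STRAND_INTERGENIC,
    STRAND_TRANSCRIBED,
    STRAND_UNTRANSCRIBED,
)

SCENARIOS = ("trunk_chemo", "branch_chemo", "no_chemo")
GROUPS = ("diagnosis", "relapse")
CHEMO_SIGNATURES = ("SBS-MM1", "SBS35")

#: default mean sequencing depths (reads); the cohort this emulates had
#: median tumor/normal coverage of 92.1X and 58.8X
DEPTH_TUMOR = 92.1
DEPTH_NORMAL = 58.8


# ---------------------------------------------------------------------------
# Bundled synthetic signature reference
# ---------------------------------------------------------------------------

# Channel blocks loosely shaped after the processes they stand in for
# (SBS1: C>T at CpG; SBS2/SBS13: C>T / C>G at TpC; SBS5: flat; SBS9:
# T>C/T>G rich; SBS-MM1: T>A/T>C rich; SBS35: C>A rich).  The profiles
# are synthetic: they are built for pairwise separation (cosine < 0.5),
# not copied from any published reference.
_BLOCKS = {
    "SBS1": [f"{f}[C>T]G" for f in "ACGT"],
    "SBS2": [f"T[C>T]{t}" for t in "ACGT"],
    "SBS13": [f"T[C>G]{t}" for t in "ACGT"],
    "SBS9": [f"{f}[T>G]{t}" for f in "AT" for t in "ACGT"]
    + [f"{f}[T>C]{t}" for f in "GC" for t in "AC"],
    "SBS-MM1": [f"{f}[T>A]{t}" for f in "ACGT" for t in "AC"]
    + [f"{f}[T>C]{t}" for f in "AT" for t in "GT"],
    "SBS35": [f"{f}[C>A]{t}" for f in "ACGT" for t in "ACGT"],
    "SBS5": [],  # flat, clock-like background
}


def synthetic_signature_reference() -> SignatureReference:
    """Bundled synthetic, well-separated signature profiles.

    Each signature puts 88% of its mass on its characteristic channel
    block and 12% uniformly everywhere (SBS5 is flat); all pairwise
    cosine similarities are below 0.5.
    """
    names = ("SBS1", "SBS2", "SBS5", "SBS9", "SBS13", "SBS-MM1", "SBS35")
    idx = {c: i for i, c in enumerate(CHANNELS_96)}
    matrix = np.zeros((96, len(names)))
    for j, name in enumerate(names):
        block = _BLOCKS[name]
        col = np.full(96, 0.12 / 96)
        if block:
            for ch in block:
                col[idx[ch]] += 0.88 / len(block)
        else:
            col = np.full(96, 1.0 / 96)
        matrix[:, j] = col / col.sum()
    return SignatureReference(names, matrix)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ClusterSpec:
    """One planted clone: parent link, per-sample CCFs, size, mixture."""

    id: str
    parent: str | None
    ccf: dict[str, float]
    n_mutations: int
    mixture: dict[str, float]


@dataclass
class SimConfig:
    """Full specification of one synthetic patient."""

    n_samples: int
    tree_spec: list[ClusterSpec]
    depth_tumor: float = DEPTH_TUMOR
    depth_normal: float = DEPTH_NORMAL
    purity: float = 0.9
    strand_bias_ratio: float = 2.0
    intergenic_fraction: float = 0.5
    scenario: str = "no_chemo"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.depth_tumor <= 0 or self.depth_normal <= 0:
            raise ValueError("depths must be positive")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must lie in (0, 1]")
        by_id = {c.id: c for c in self.tree_spec}
        for c in self.tree_spec:
            if c.n_mutations < 0:
                raise ValueError(f"cluster {c.id}: negative mutation count")
            if any(not 0 <= v <= 1 for v in c.ccf.values()):
                raise ValueError(f"cluster {c.id}: CCF outside [0, 1]")
            total = sum(c.mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"cluster {c.id}: mixture sums to {total}")
            if c.parent is not None:
                if c.parent not in by_id:
                    raise ValueError(f"cluster {c.id}: unknown parent {c.parent}")
                parent = by_id[c.parent]
                bad = [s for s, v in c.ccf.items() if v > parent.ccf[s] + 1e-9]
                if bad:
                    raise ValueError(
                        f"cluster {c.id} violates pigeonhole vs {c.parent} "
                        f"in sample(s) {bad}"
                    )

    @property
    def samples(self) -> list[str]:
        return sorted(self.tree_spec[0].ccf)

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        d = yaml.safe_load(text)
        d["tree_spec"] = [ClusterSpec(**c) for c in d["tree_spec"]]
        return cls(**d)


@dataclass
class TruthSet:
    """Ground truth for one simulated patient."""

    cluster_ids: list[str]
    signatures: list[str]
    cluster_ccf: dict[str, dict[str, float]]
    tree_parent: dict[str, str | None]
    scenario: str
    planted_ratio: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "cluster_ccf": self.cluster_ccf,
                "tree_parent": self.tree_parent,
                "scenario": self.scenario,
                "planted_ratio": self.planted_ratio,
            },
            indent=2,
            sort_keys=True,
        )

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"cluster": self.cluster_ids, "signature": self.signatures}
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Patient simulation
# ---------------------------------------------------------------------------


def _channel_parts(channel: str) -> tuple[str, str, str, str]:
    # "A[C>T]G" -> five, ref, alt, three
    return channel[0], channel[2], channel[4], channel[6]


def simulate_patient(
    config: SimConfig,
    signatures: SignatureReference | None = None,
) -> tuple[list[MutationRecord], TruthSet]:
    """Draw one patient's mutation table and its ground truth.

    Per cluster, each mutation's channel is drawn from the cluster's
    signature mixture; per sample, depth ~ Poisson(depth_tumor) and
    alt ~ Binomial(depth, purity * CCF / 2).  Chemotherapy-signature
    mutations get transcribed:untranscribed strand odds equal to
    ``strand_bias_ratio``; all others get even odds; an
    ``intergenic_fraction`` of mutations is unstranded.  Fixed
    ``rng_seed`` gives byte-identical output.
    """
    ref = signatures or synthetic_signature_reference()
    for c in config.tree_spec:
        unknown = [s for s in c.mixture if s not in ref.names]
        if unknown:
            raise ValueError(f"cluster {c.id}: unknown signature(s) {unknown}")
    rng = np.random.default_rng(config.rng_seed)
    samples = config.samples
    p_trans_chemo = config.strand_bias_ratio / (1.0 + config.strand_bias_ratio)

    mutations: list[MutationRecord] = []
    cluster_ids: list[str] = []
    origins: list[str] = []
    pos = 0
    for c in config.tree_spec:
        sig_names = [s for s in c.mixture if c.mixture[s] > 0]
        weights = np.array([c.mixture[s] for s in sig_names])
        weights = weights / weights.sum() if sig_names else weights
        which = rng.choice(len(sig_names), size=c.n_mutations, p=weights)
        for i in range(c.n_mutations):
            pos += 1
            sig = sig_names[which[i]]
            channel_i = rng.choice(96, p=ref.column(sig))
            channel = CHANNELS_96[channel_i]
            five, base_ref, base_alt, three = _channel_parts(channel)
            # half the records are written on the purine strand, as in
            # real call sets; the channel is strand-collapsed already
            if rng.random() < 0.5:
                base_ref, base_alt = COMPLEMENT[base_ref], COMPLEMENT[base_alt]
            if rng.random() < config.intergenic_fraction:
                strand = STRAND_INTERGENIC
            else:
                p_t = p_trans_chemo if sig in CHEMO_SIGNATURES else 0.5
                strand = (
                    STRAND_TRANSCRIBED if rng.random() < p_t else STRAND_UNTRANSCRIBED
                )
            per_sample = {}
            for s in samples:
                depth = int(rng.poisson(config.depth_tumor))
                vaf = config.purity * c.ccf[s] / 2.0
                alt = int(rng.binomial(depth, vaf)) if depth > 0 else 0
                per_sample[s] = (alt, depth)
            mutations.append(
                MutationRecord(
                    chrom="1",
                    pos=pos,
                    ref=base_ref,
                    alt=base_alt,
                    context96=channel,
                    strand=strand,
                    per_sample=per_sample,
                )
            )
            cluster_ids.append(c.id)
            origins.append(sig)

    truth = TruthSet(
        cluster_ids=cluster_ids,
        signatures=origins,
        cluster_ccf={c.id: dict(c.ccf) for c in config.tree_spec},
        tree_parent={c.id: c.parent for c in config.tree_spec},
        scenario=config.scenario,
    )
    return mutations, truth


# ---------------------------------------------------------------------------
# Default patient and cohort construction
# ---------------------------------------------------------------------------

_BASE_MIX = {"SBS1": 0.20, "SBS5": 0.30, "SBS9": 0.20, "SBS2": 0.15, "SBS13": 0.15}
_BRANCH_MIX = {"SBS1": 0.20, "SBS5": 0.35, "SBS2": 0.25, "SBS13": 0.20}
_CHEMO_WEIGHT = 0.25


def _with_chemo(mixture: dict[str, float], chemo: str, weight: float) -> dict[str, float]:
    scaled = {k: v * (1 - weight) for k, v in mixture.items()}
    scaled[chemo] = weight
    return scaled


def scenario_tree_spec(scenario: str, n_samples: int = 3) -> list[ClusterSpec]:
    """Default clone tree for a scenario patient.

    Trunk of 3500 mutations clonal everywhere, three sample-private
    first-level branches and one nested branch (~7,000 mutations in
    total, within the whole-genome mutation loads seen in this disease).
    ``trunk_chemo`` plants the melphalan barcode (weight 0.25) in the
    trunk; ``branch_chemo`` plants it in two branches on disjoint
    trajectories.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if n_samples < 2:
        raise ValueError("need at least two anatomic sites")
    names = [f"site{j}" for j in range(n_samples)]

    def ccf(**kw) -> dict[str, float]:
        return {s: kw.get(s, 0.0) for s in names}

    trunk_mix = dict(_BASE_MIX)
    b1_mix, b2_mix = dict(_BRANCH_MIX), dict(_BRANCH_MIX)
    if scenario == "trunk_chemo":
        trunk_mix = _with_chemo(trunk_mix, "SBS-MM1", _CHEMO_WEIGHT)
    elif scenario == "branch_chemo":
        b1_mix = _with_chemo(b1_mix, "SBS-MM1", _CHEMO_WEIGHT)
        b2_mix = _with_chemo(b2_mix, "SBS-MM1", _CHEMO_WEIGHT)

    spec = [
        ClusterSpec("trunk", None, {s: 1.0 for s in names}, 3500, trunk_mix),
        ClusterSpec("b1", "trunk", ccf(site0=0.75), 1000, b1_mix),
        ClusterSpec("b2", "trunk", ccf(site1=0.70), 1000, b2_mix),
        ClusterSpec("b1a", "b1", ccf(site0=0.35), 600, dict(_BRANCH_MIX)),
    ]
    if n_samples >= 3:
        spec.append(ClusterSpec("b3", "trunk", ccf(site2=0.65), 900, dict(_BRANCH_MIX)))
    return spec


def patient_config(scenario: str, seed: int = 0, n_samples: int = 3, **overrides) -> SimConfig:
    """A default scenario patient (see :func:`scenario_tree_spec`)."""
    return SimConfig(
        n_samples=n_samples,
        tree_spec=scenario_tree_spec(scenario, n_samples),
        scenario=scenario,
        rng_seed=seed,
        **overrides,
    )


def _ratio_tree_spec(
    planted_ratio: float,
    scenario: str,
    n_samples: int,
    trunk_n: int = 3500,
) -> list[ClusterSpec]:
    """Tree whose planted branch:trunk SBS1 ratio equals ``planted_ratio``.

    Each branch is a private first-level child (one trajectory each)
    carrying SBS1 counts of ``planted_ratio`` times the trunk's, so the
    trajectory-averaged planted ratio is exactly ``planted_ratio``.
    """
    names = [f"site{j}" for j in range(n_samples)]
    trunk_mix = dict(_BASE_MIX)
    if scenario == "trunk_chemo":
        trunk_mix = _with_chemo(trunk_mix, "SBS-MM1", _CHEMO_WEIGHT)
    trunk_sbs1 = trunk_n * trunk_mix["SBS1"] / (
        sum(trunk_mix.values())
    )
    spec = [ClusterSpec("trunk", None, {s: 1.0 for s in names}, trunk_n, trunk_mix)]
    branch_ccfs = [0.75, 0.70, 0.65]
    for j in range(min(n_samples, 3)):
        target_sbs1 = planted_ratio * trunk_sbs1
        n_b = max(200, int(np.ceil(target_sbs1 / 0.4)))
        w_sbs1 = target_sbs1 / n_b
        rest = {k: v for k, v in _BRANCH_MIX.items() if k != "SBS1"}
        scale = (1.0 - w_sbs1) / sum(rest.values())
        mixture = {k: v * scale for k, v in rest.items()}
        mixture["SBS1"] = w_sbs1
        ccf = {s: 0.0 for s in names}
        ccf[names[j]] = branch_ccfs[j]
        spec.append(ClusterSpec(f"b{j + 1}", "trunk", ccf, n_b, mixture))
    return spec


def simulate_cohort(
    n_patients: int,
    group: str,
    master_seed: int = 0,
    n_samples: int = 3,
    planted_ratio_mean: float | None = None,
    signatures: SignatureReference | None = None,
    **config_overrides,
) -> list[tuple[list[MutationRecord], TruthSet]]:
    """Simulate a diagnosis-like or relapse-like patient group.

    ``diagnosis`` patients diverged early (planted branch:trunk SBS1
    ratio mean 0.8, no chemotherapy barcode); ``relapse`` patients
    diverged late after treatment (ratio mean 0.1, melphalan barcode in
    the trunk).  Per-patient ratios are Gamma-distributed (shape 4)
    around the group mean; per-patient seeds derive from ``master_seed``
    by counter-based splitting, so cohorts are reproducible.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r} (expected one of {GROUPS})")
    mean = planted_ratio_mean if planted_ratio_mean is not None else (
        0.8 if group == "diagnosis" else 0.1
    )
    scenario = "no_chemo" if group == "diagnosis" else "trunk_chemo"
    children = np.random.SeedSequence(master_seed).spawn(n_patients)
    out = []
    for child in children:
        child_rng = np.random.default_rng(child)
        ratio = float(child_rng.gamma(shape=4.0, scale=mean / 4.0))
        seed = int(child_rng.integers(0, 2**31 - 1))
        cfg = SimConfig(
            n_samples=n_samples,
            tree_spec=_ratio_tree_spec(ratio, scenario, n_samples),
            scenario=scenario,
            rng_seed=seed,
            **config_overrides,
        )
        muts, truth = simulate_patient(cfg, signatures)
        truth.planted_ratio = ratio
        out.append((muts, truth))
    return out
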