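"""Dirichlet-process clustering of mutations in multi-sample CCF space.

Mutations from multi-region sequencing of one patient are clustered on
their cancer cell fractions (CCF) jointly across samples.  The emission
model is binomial: a mutation in cluster ``k`` with per-sample cluster
CCF ``c_ks`` yields ``alt ~ Binomial(depth, purity_s * c_ks / 2)`` at a
diploid locus.  The mixture over clusters is a Dirichlet process,
approximated by a truncated stick-breaking representation and sampled
with a blocked Gibbs sampler:

1. stick weights  v_k ~ Beta(1 + n_k, alpha + n_{>k});
2. cluster success probabilities from their Beta posterior, mapped back
   to CCF via c = 2 p / purity and clipped to [0, 1] (empty clusters
   redraw their CCF uniformly);
3. assignments from the categorical posterior, vectorised over all
   mutations;
4. the concentration alpha from its conditional under a Gamma prior.

The point estimate is the per-mutation modal cluster label across
post-burn-in sweeps after relabelling each sweep to a maximum-likelihood
reference sweep (Hungarian matching on cluster centres); cluster CCF
centres are posterior means over matched sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .catalogs import MutationRecord, count_matrices

logger = logging.getLogger("chemobarcode.dp")


@dataclass
class DPConfig:
    """Sampler and filtering configuration.

    ``concentration_prior`` is the (shape, rate) of the Gamma prior on
    the DP concentration.  ``min_cluster_size`` implements the strict
    "more than 50 mutations" cluster filter; ``donor_snp_ccf_threshold``
    the low-CCF all-sample rule used for allogeneic-transplant patients
    whose donor SNPs masquerade as a shared subclonal cluster.
    """

    concentration_prior: tuple[float, float] = (1.0, 1.0)
    truncation: int = 20
    n_iterations: int = 2000
    burn_in: int = 1000
    rng_seed: int = 0
    min_cluster_size: int = 50
    donor_snp_ccf_threshold: float = 0.10
    thin: int = 5
    #: post-hoc merge radius: clusters whose centres differ by less than
    #: this in every sample are indistinguishable at typical depths and
    #: are merged (0 disables merging)
    merge_tolerance: float = 0.05

    def __post_init__(self) -> None:
        self.concentration_prior = tuple(self.concentration_prior)
        if self.truncation < 1:
            raise ValueError("truncation must be >= 1")
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.min_cluster_size < 0:
            raise ValueError("min_cluster_size must be >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class CloneCluster:
    """A clone: its per-sample CCF centre and member mutations."""

    id: str
    ccf: dict[str, float]
    members: list[int] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    def ccf_vector(self, samples: list[str]) -> np.ndarray:
        return np.array([self.ccf[s] for s in samples])


class DPResults:
    """Posterior summary of a :class:`DirichletProcessModel` fit."""

    def __init__(
        self,
        model: "DirichletProcessModel",
        assignments: np.ndarray,
        clusters: list[CloneCluster],
        n_sweeps_used: int,
    ):
        self.model = model
        self.assignments = assignments
        self.clusters = clusters
        self.n_sweeps_used = n_sweeps_used

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        samples = self.model.samples
        by_id = {c.id: c for c in self.clusters}
        rows = []
        for i, cid in enumerate(self.assignments):
            row = {"mutation": i, "cluster": cid}
            for s in samples:
                row[f"ccf/{s}"] = by_id[cid].ccf[s]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Dirichlet-process CCF clustering",
            f"  mutations: {self.model.alt.shape[0]}   samples: {len(self.model.samples)}",
            f"  clusters found: {self.n_clusters} (truncation {self.model.config.truncation})",
            f"  post-burn-in sweeps used: {self.n_sweeps_used}",
        ]
        for c in self.clusters:
            ccfs = "  ".join(f"{s}={c.ccf[s]:.3f}" for s in self.model.samples)
            lines.append(f"  {c.id}: size {c.size:5d}   {ccfs}")
        return "\n".join(lines)


class DirichletProcessModel:
    """Truncated-DP binomial mixture over per-sample mutation counts.

    Parameters
    ----------
    alt, depth : (n_mutations, n_samples) integer arrays
    purity : per-sample tumor purity in (0, 1]
    samples : sample names (defaults to s0..s{S-1})
    config : :class:`DPConfig`
    """

    def __init__(
        self,
        alt: np.ndarray,
        depth: np.ndarray,
        purity: np.ndarray,
        samples: list[str] | None = None,
        config: DPConfig | None = None,
    ):
        alt = np.asarray(alt, dtype=np.int64)
        depth = np.asarray(depth, dtype=np.int64)
        if alt.shape != depth.shape or alt.ndim != 2:
            raise ValueError("alt and depth must be (n, S) arrays of equal shape")
        purity = np.asarray(purity, dtype=float)
        if purity.shape != (alt.shape[1],):
            raise ValueError("purity must have one entry per sample")
        if np.any((purity <= 0) | (purity > 1)):
            raise ValueError("purities must lie in (0, 1]")
        if np.any(depth.sum(axis=1) == 0):
            raise ValueError("mutation with zero depth in every sample")
        if np.any(alt > depth):
            raise ValueError("alt_count exceeds depth")
        self.alt, self.depth, self.purity = alt, depth, purity
        self.samples = samples or [f"s{j}" for j in range(alt.shape[1])]
        self.config = config or DPConfig()

    @classmethod
    def from_mutations(
        cls,
        mutations: list[MutationRecord],
        purity: dict[str, float],
        config: DPConfig | None = None,
    ) -> "DirichletProcessModel":
        alt, depth, samples = count_matrices(mutations)
        missing = [s for s in samples if s not in purity]
        if missing:
            raise ValueError(f"missing purity for sample(s) {missing}")
        pur = np.array([purity[s] for s in samples])
        return cls(alt, depth, pur, samples=samples, config=config)

    # -- Gibbs sampler -----------------------------------------------------

    def fit(self, seed: int | None = None) -> DPResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
        n, S = self.alt.shape
        K = cfg.truncation
        alt = self.alt.astype(float)
        ref_counts = (self.depth - self.alt).astype(float)
        # single (n, 2S) count block so the likelihood is one matmul;
        # float32 halves memory traffic in the hot loop
        counts32 = np.concatenate([alt, ref_counts], axis=1).astype(np.float32)
        a0, b0 = cfg.concentration_prior
        alpha = 1.0

        ccf = rng.uniform(size=(K, S))
        log_w = np.full(K, -np.log(K))

        kept_z: list[np.ndarray] = []
        kept_ccf: list[np.ndarray] = []
        kept_ll: list[float] = []

        for it in range(cfg.n_iterations):
            # assignments | weights, centres
            p = np.clip(self.purity[None, :] * ccf / 2.0, 1e-12, 1 - 1e-12)
            logp_block = np.concatenate(
                [np.log(p), np.log1p(-p)], axis=1
            ).astype(np.float32)  # (K, 2S)
            ll = counts32 @ logp_block.T  # (n, K)
            logits = ll + log_w[None, :].astype(np.float32)
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            cum = probs.cumsum(axis=1)
            u = (rng.random(n) * cum[:, -1]).astype(np.float32)
            z = np.minimum((cum < u[:, None]).sum(axis=1), K - 1)

            # stick weights | assignments
            nk = np.bincount(z, minlength=K).astype(float)
            n_gt = nk[::-1].cumsum()[::-1] - nk
            v = rng.beta(1.0 + nk, alpha + n_gt)
            v = np.clip(v, 1e-12, 1 - 1e-12)
            v[-1] = 1.0 - 1e-12
            log1mv = np.log1p(-v)
            log_w = np.log(v) + np.concatenate(([0.0], np.cumsum(log1mv[:-1])))

            # concentration | sticks  (Gamma prior (a0, b0))
            alpha = rng.gamma(a0 + K - 1, 1.0 / (b0 - log1mv[:-1].sum()))

            # centres | assignments (Beta-conjugate on p, mapped to CCF)
            A = np.zeros((K, S))
            D = np.zeros((K, S))
            for s in range(S):
                A[:, s] = np.bincount(z, weights=alt[:, s], minlength=K)
                D[:, s] = np.bincount(z, weights=self.depth[:, s], minlength=K)
            p_post = rng.beta(1.0 + A, 1.0 + (D - A))
            ccf = np.clip(2.0 * p_post / self.purity[None, :], 0.0, 1.0)
            empty = nk == 0
            if empty.any():
                ccf[empty] = rng.uniform(size=(int(empty.sum()), S))

            if (it + 1) % 500 == 0:
                logger.debug(
                    "sweep %d: %d occupied clusters, alpha=%.3f",
                    it + 1, int((nk > 0).sum()), alpha,
                )
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                kept_z.append(z.astype(np.int16))
                kept_ccf.append(ccf.copy())
                kept_ll.append(float(ll[np.arange(n), z].sum()))

        return self._summarise(kept_z, kept_ccf, kept_ll)

    def _summarise(
        self,
        kept_z: list[np.ndarray],
        kept_ccf: list[np.ndarray],
        kept_ll: list[float],
    ) -> DPResults:
        """Relabel sweeps against the best-likelihood sweep, take modal
        assignments, merge indistinguishable fragments, and report
        posterior-mean centres given the final assignment."""
        n, S = self.alt.shape
        K = self.config.truncation
        ref_t = int(np.argmax(kept_ll))
        ref_z, ref_ccf = kept_z[ref_t], kept_ccf[ref_t]
        ref_occ = np.flatnonzero(np.bincount(ref_z, minlength=K) > 0)

        votes = np.zeros((n, K), dtype=np.int32)
        for z, c in zip(kept_z, kept_ccf):
            occ = np.flatnonzero(np.bincount(z, minlength=K) > 0)
            cost = ((c[occ][:, None, :] - ref_ccf[ref_occ][None, :, :]) ** 2).sum(-1)
            ri, ci = linear_sum_assignment(cost)
            # clusters without a reference partner get a free label
            mapping = np.arange(K)
            used = set()
            for a, b in zip(ri, ci):
                mapping[occ[a]] = ref_occ[b]
                used.add(int(ref_occ[b]))
            matched = {int(occ[a]) for a in ri}
            free = iter(k for k in range(K) if k not in used)
            for a in occ:
                if int(a) not in matched:
                    lab = int(a) if int(a) not in used else next(free)
                    mapping[a] = lab
                    used.add(lab)
            votes[np.arange(n), mapping[z]] += 1

        final = votes.argmax(axis=1)
        labels = np.unique(final)

        def _centre(mask: np.ndarray) -> np.ndarray:
            # Beta posterior mean of the success probability given the
            # assignment, mapped back to CCF
            A = self.alt[mask].sum(axis=0)
            D = self.depth[mask].sum(axis=0)
            p = (A + 1.0) / (D + 2.0)
            return np.clip(2.0 * p / self.purity, 0.0, 1.0)

        centres = np.stack([_centre(final == lab) for lab in labels])

        # merge posterior fragments: components closer than merge_tolerance
        # in every sample are one clone at realistic depths
        groups = [[lab] for lab in labels]
        group_centres = list(centres)
        tol = self.config.merge_tolerance
        while len(groups) > 1:
            dists = np.full((len(groups), len(groups)), np.inf)
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    dists[i, j] = np.abs(group_centres[i] - group_centres[j]).max()
            i, j = np.unravel_index(np.argmin(dists), dists.shape)
            if dists[i, j] >= tol:
                break
            groups[i] += groups[j]
            group_centres[i] = _centre(np.isin(final, groups[i]))
            del groups[j], group_centres[j]

        order = np.argsort([-c.sum() for c in group_centres], kind="stable")
        clusters = []
        for rank, pos in enumerate(order):
            members = np.flatnonzero(np.isin(final, groups[pos])).tolist()
            ccf = {s: float(group_centres[pos][j]) for j, s in enumerate(self.samples)}
            clusters.append(CloneCluster(id=f"cl{rank}", ccf=ccf, members=members))
        assignments = np.empty(n, dtype=object)
        for c in clusters:
            assignments[c.members] = c.id
        return DPResults(self, assignments, clusters, n_sweeps_used=len(kept_z))


def dp_cluster(
    mutations: list[MutationRecord],
    purity: dict[str, float],
    config: DPConfig | None = None,
) -> list[CloneCluster]:
    """Cluster mutations in multi-sample CCF space (functional shorthand)."""
    model = DirichletProcessModel.from_mutations(mutations, purity, config)
    return model.fit().clusters


# ---------------------------------------------------------------------------
# Cluster filters
# ---------------------------------------------------------------------------


@dataclass
class FilterOutcome:
    kept: list[CloneCluster]
    removed_small: list[CloneCluster]
    donor_flagged: list[CloneCluster]


def filter_clusters(
    clusters: list[CloneCluster],
    config: DPConfig | None = None,
    allo_mode: bool = False,
    detailed: bool = False,
):
    """Apply the cluster-size and donor-SNP filters.

    Clusters must have strictly more than ``min_cluster_size`` mutations
    to be retained.  In ``allo_mode`` (patient received an allogeneic
    transplant), a cluster present in every sample whose median CCF is
    below ``donor_snp_ccf_threshold`` is flagged as a putative
    donor-SNP cluster and removed: germline variants private to the
    donor appear as a shared low-CCF mutation cluster.
    """
    cfg = config or DPConfig()
    kept: list[CloneCluster] = []
    removed_small: list[CloneCluster] = []
    donor_flagged: list[CloneCluster] = []
    for c in clusters:
        if c.size <= cfg.min_cluster_size:
            removed_small.append(c)
            continue
        if allo_mode:
            ccfs = np.array(list(c.ccf.values()))
            present_all = bool(np.all(ccfs > 0.01))
            if present_all and float(np.median(ccfs)) < cfg.donor_snp_ccf_threshold:
                c.flags.append("putative_donor_snp")
                donor_flagged.append(c)
                continue
        kept.append(c)
    if detailed:
        return FilterOutcome(kept, removed_small, donor_flagged)
    return kept
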