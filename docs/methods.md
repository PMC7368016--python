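# Methods

This note documents the models, defaults and numerical choices behind
`chemobarcode`, and what the synthetic cohorts do and do not emulate.

## Signature exposure model

A catalog `m` of `n` mutations over the 96 pyrimidine-centred
trinucleotide channels is modelled as multinomial with channel
probabilities `q = P w`, where `P` is the (96 × J) signature reference
and `w` the exposure weights on the simplex. `w` is estimated by EM
(iterative proportional fitting), which for this model converges to the
global maximum-likelihood solution; convergence tolerance 1e-9 on the
max weight change, at most 10,000 iterations.

**Backward elimination.** After the full fit, the smallest-exposure
signature is tentatively dropped and the model refitted; the drop is
accepted while the cosine similarity between observed and reconstructed
profiles decreases by less than `elimination_threshold` (default 0.01).
Elimination is a *presence call*, not an unbiased estimator: it
deliberately zeroes weakly supported exposures. Two consequences are
documented and respected throughout:

* recovery properties (e.g. mean absolute error of exposures on random
  mixtures) are measured on the plain ML fit (`elimination_threshold=None`);
* profiles that overlap a flat background — SBS35's spread-out C>A
  block against flat SBS5, and likewise SBS-MM1 — can be absorbed with
  a cosine change below the threshold when catalogs are small. The
  pooled chemotherapy fraction of nonsynonymous mutations therefore
  fits the cohort-pooled catalog and applies no elimination (the active
  signature set is established beforehand on genome-wide catalogs).
  This mirrors the known SBS5/SBS-MM1/SBS35 assignment ambiguity that
  motivates using SBS1, not SBS5, as the evolutionary clock.

**Bootstrap CIs.** 1000 catalogs of size `n` are redrawn from the
observed channel proportions; each is refitted and per-signature
2.5th/97.5th percentiles reported. Replicate refits use the signature
set retained by elimination on the observed catalog and run in a single
vectorised batch; repeating elimination inside every replicate would
change intervals only for signatures at the elimination boundary and is
not offered. Observed-catalog resampling (not reconstructed-catalog) is
the implemented definition.

**Strand bias.** Transcription-coupled repair of adduct-forming agents
leaves an excess of mutations on one strand. The test is a two-sided
exact binomial test of transcribed vs untranscribed counts against 0.5,
significant below 0.05. Mutations are attributed to a signature when
the fitted model's posterior probability for that signature given the
mutation's channel is at least 0.5; intergenic/unknown-strand mutations
are excluded.

## Dirichlet-process CCF clustering

Per mutation and sample, `alt ~ Binomial(depth, purity × CCF / 2)` at a
diploid locus; purity is an input, not estimated, and copy number is
fixed diploid. The mixture over clones is a Dirichlet process truncated
at `truncation` components (default 20), sampled by blocked Gibbs:

1. stick weights `v_k ~ Beta(1 + n_k, α + n_{>k})`;
2. per-sample success probabilities from their Beta posterior, mapped
   to CCF by `c = 2p/purity` and clipped to [0, 1] — the clip makes the
   sampler approximate at the clonal boundary, which in practice only
   concentrates mass at CCF = 1 where it belongs; empty components
   redraw CCFs uniformly;
3. assignments from the categorical posterior, vectorised (float32
   likelihood block; one matmul per sweep);
4. concentration α from its Gamma(1, 1)-prior conditional.

Defaults: 2000 sweeps, burn-in 1000, thinning 5, all configurable.
The point estimate is the per-mutation modal label across post-burn-in
sweeps after relabelling every sweep to the maximum-likelihood sweep by
Hungarian matching of cluster centres. Because the DP posterior often
splits one clone across neighbouring components, clusters whose centres
differ by less than `merge_tolerance` (default 0.05, about twice the
CCF standard error at 90X with ≥100 mutations) in every sample are
merged. Final centres are Beta-posterior means of the pooled member
counts given the final assignment — this is robust to label drift
across sweeps, which contaminates averaged per-sweep centres.

**Filters.** Only clusters with strictly more than `min_cluster_size`
(default 50) mutations are kept. In allogeneic-transplant mode, a
cluster present in every sample (CCF > 0.01) whose median CCF is below
`donor_snp_ccf_threshold` (default 0.10) is flagged as a putative
donor-SNP cluster and removed: donor germline variants appear as a
shared low-CCF "subclone" in every sample.

## Pigeonhole tree construction

A valid clone tree must satisfy, in every sample, child CCF ≤ parent
CCF and the sibling-sum constraint Σ(children CCF) ≤ parent CCF. The
trunk is the cluster clonal everywhere (CCF ≥ `clonal_ccf_threshold`,
default 0.85); remaining clusters attach greedily in decreasing order
of summed CCF, each to its *deepest* feasible parent (smallest summed
CCF among feasible candidates), ties broken by cluster id. Both
thresholds absorb centre noise (`tolerance` default 0.05). A cluster
with no feasible parent raises an error naming the violated samples.
The greedy deterministic rule is a stand-in for "the most likely tree":
no likelihood over topologies is defined, and trees whose planted
parent is not the deepest feasible parent are not identifiable from CCF
constraints alone. One trajectory is enumerated per leaf (trunk → leaf
path).

## Seeding classification and the SBS1 ratio

A chemotherapy signature (SBS-MM1, SBS35) is **detected** in a node
when its exposure proportion is ≥ `detection_threshold` (default 0.05)
*and* its bootstrap lower bound is positive. Scenario rules: trunk
detection only → `single_cell_seeding`; trunk plus branch detections →
`mixed`; branch detections without trunk → `preexisting_clones` (also
when only a single branch is detected: a barcode private to one lineage
implies that lineage predated the exposure); none → `no_chemo_signature`.

Per-node SBS1 counts are exposure proportion × cluster size (raw
C>T-at-CpG channel counts overlap other processes). For each
trajectory, branch SBS1 is summed over the trajectory's non-trunk
nodes; the patient ratio is the **mean over trajectories** of
branch/trunk — the correction that never pools mutations acquired in
parallel lineages. Median/sum variants of the correction were
considered; the mean is the implemented default because it weights each
independent lineage equally. Group contrasts use the two-sided Wilcoxon
rank-sum test.

## Synthetic cohorts

The generator emulates multi-region whole-genome sequencing of one
patient: a planted clone tree (pigeonhole-consistent by construction),
cluster-specific signature mixtures over the bundled reference,
Poisson depth around 92.1X tumor / 58.8X normal (the coverage regime
of the cohorts this emulates), binomial alt counts at
`VAF = purity × CCF / 2` (default purity 0.9, reflecting CD138+
purified samples), and strand labels with transcribed:untranscribed
odds `strand_bias_ratio` (default 2.0) for chemotherapy-signature
mutations, even odds otherwise; 50% of mutations are intergenic and
unstranded. Default scenario patients have a 3500-mutation trunk,
three sample-private branches and one nested branch (~7,000 mutations),
within the 7,000–13,000 whole-genome range typical of this disease;
chemotherapy weight 0.25 is planted in the trunk (`trunk_chemo`) or in
two disjoint branches (`branch_chemo`).

Cohorts plant the branch:trunk SBS1 ratio directly: per patient a ratio
is drawn from Gamma(shape 4) with mean 0.8 (diagnosis-like, early
divergence, no chemotherapy) or 0.1 (relapse-like, late divergence,
melphalan barcode in the trunk), and branch sizes/SBS1 weights are set
so the planted trajectory-averaged ratio equals the draw. Per-patient
seeds derive from the master seed via `numpy` `SeedSequence.spawn`
(counter-based splitting), so cohorts are exactly reproducible.

**The bundled signature reference is synthetic.** Seven profiles carry
the names of the processes they stand in for (SBS1, SBS2, SBS5, SBS9,
SBS13, SBS-MM1, SBS35) and loosely their characteristic channel blocks
(SBS1: C>T at CpG; SBS2/13: C>T / C>G at TpC; flat SBS5; …), but the
vectors are constructed for pairwise separation (all cosines < 0.5),
not copied from any published reference; a real COSMIC-format file can
be supplied instead. Consequences: passing tests demonstrate the
correctness of the inference machinery under the stated noise model,
not performance under the true (more collinear) COSMIC profiles, CNA-
distorted CCFs, sequencing artefacts, or clustered mutational processes
— none of which the generator emulates (indels, SVs, CNAs, kataegis and
realistic genome coordinates are out of scope).

## Problem sizes and determinism

Acceptance-level checks run at the study scale chosen for this package:
60 end-to-end patients (20 per scenario) for classification accuracy,
20 patients per arm for the ratio contrast, 200 simulations × 1000
bootstrap draws for CI calibration, 100 trials for exposure recovery,
and 100 random trees (≤ 8 nodes, exhaustively oracle-checked) for
topology recovery. Every stochastic component takes an explicit seed;
reruns with the same configuration are byte-identical, and per-patient
seeds in cohort runs are spawned deterministically from the master
seed.

## Known limitations

* CCFs assume diploid loci; CNA-adjusted multiplicity is out of scope,
  so real catalogs should be restricted to copy-neutral regions first.
* The greedy tree is deterministic and reports no uncertainty; near-tie
  attachments at tolerance boundaries can flip with centre noise.
* Cosine-based elimination is insensitive to flat-vs-spread profile
  trades (see above); detection of low chemotherapy exposures
  (< ~5%) in small clusters is conservative by design.
* The DP sampler's truncation and clipped CCF mapping are pragmatic;
  posterior uncertainty of cluster centres is not propagated into the
  tree.
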