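"""Mutational-signature exposure fitting with bootstrap confidence intervals.

The model: an observed 96-channel catalog ``m`` with ``n`` mutations is
treated as a multinomial draw whose channel probabilities are a convex
combination ``sum_j w_j P[:, j]`` of known signature profiles.  The
exposure weights ``w`` (non-negative, summing to one) are estimated by
maximum likelihood via EM, followed by backward elimination of weakly
supported signatures: the smallest-exposure signature is dropped and the
model refitted as long as the cosine similarity between the observed and
reconstructed profiles decreases by less than ``elimination_threshold``.

Confidence intervals follow the multinomial bootstrap: 1000 catalogs of
size ``n`` are redrawn from the observed channel proportions, each refit,
and the 2.5th/97.5th exposure percentiles reported per signature.

``SignatureModel`` / ``SignatureFitResults`` mirror the statsmodels
model/results idiom; :func:`fit_exposures` and :func:`bootstrap_ci` are
functional shorthands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalogs import CHANNELS_96, Catalog, MutationRecord, SignatureReference, STRANDED

_EPS = 1e-300


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _em(m: np.ndarray, P: np.ndarray, tol: float = 1e-9, max_iter: int = 10_000) -> np.ndarray:
    """EM / iterative proportional fitting for multinomial mixture weights."""
    n = m.sum()
    J = P.shape[1]
    w = np.full(J, 1.0 / J)
    for _ in range(max_iter):
        r = np.maximum(P @ w, _EPS)
        w_new = w * (P.T @ (m / r)) / n
        w_new /= w_new.sum()
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    return w


def _em_batch(
    M: np.ndarray, P: np.ndarray, tol: float = 1e-7, max_iter: int = 2_000
) -> np.ndarray:
    """Vectorised EM over B catalogs sharing one signature matrix.

    M is (96, B) counts; returns W of shape (J, B).
    """
    n = M.sum(axis=0)
    J, B = P.shape[1], M.shape[1]
    W = np.full((J, B), 1.0 / J)
    active = np.ones(B, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Wa = W[:, idx]
        R = np.maximum(P @ Wa, _EPS)
        W_new = Wa * (P.T @ (M[:, idx] / R)) / n[idx]
        W_new /= W_new.sum(axis=0, keepdims=True)
        done = np.abs(W_new - Wa).max(axis=0) < tol
        W[:, idx] = W_new
        active[idx[done]] = False
    return W


@dataclass
class SignatureFitResults:
    """Fitted signature exposures for one catalog.

    Proportions are reported over the full input reference; eliminated
    signatures carry proportion zero.  ``ci_low``/``ci_high`` are NaN
    until :meth:`conf_int` (or :func:`bootstrap_ci`) has been run.
    """

    model: "SignatureModel"
    signatures: tuple[str, ...]
    proportions: np.ndarray
    retained: tuple[str, ...]
    reconstruction_cosine: float
    n_total: int
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_boot: int | None = None

    @property
    def counts(self) -> np.ndarray:
        return self.proportions * self.n_total

    def proportion(self, signature: str) -> float:
        return float(self.proportions[self.signatures.index(signature)])

    def count(self, signature: str) -> float:
        return float(self.counts[self.signatures.index(signature)])

    def conf_int(
        self, n_boot: int = 1000, seed: int | np.random.Generator | None = None,
        alpha: float = 0.05,
    ) -> "SignatureFitResults":
        """Multinomial bootstrap percentile intervals (in place).

        Draws ``n_boot`` catalogs of size ``n_total`` from the observed
        channel proportions and refits the retained signatures to each;
        the interval is the [100*alpha/2, 100*(1-alpha/2)] percentile
        range per signature.  Eliminated signatures get [0, 0].
        """
        if n_boot < 2:
            raise ValueError("n_boot must be at least 2")
        rng = np.random.default_rng(seed)
        m = self.model.counts
        p_obs = m / m.sum()
        M = rng.multinomial(self.n_total, p_obs, size=n_boot).T.astype(float)
        keep_idx = [self.signatures.index(s) for s in self.retained]
        P = self.model.reference.matrix[:, keep_idx]
        W = _em_batch(M, P)
        lo = np.zeros(len(self.signatures))
        hi = np.zeros(len(self.signatures))
        q = np.percentile(W, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=1)
        for row, j in enumerate(keep_idx):
            lo[j], hi[j] = q[0, row], q[1, row]
        self.ci_low, self.ci_high, self.n_boot = lo, hi, n_boot
        return self

    def posterior_channel_probabilities(self) -> np.ndarray:
        """(96, n_signatures) posterior P(signature | channel) under the fit."""
        P = self.model.reference.matrix
        r = np.maximum(P @ self.proportions, _EPS)
        return (P * self.proportions[None, :]) / r[:, None]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "signature": list(self.signatures),
                "count": self.counts,
                "proportion": self.proportions,
            }
        )
        df["ci_low"] = self.ci_low if self.ci_low is not None else np.nan
        df["ci_high"] = self.ci_high if self.ci_high is not None else np.nan
        return df

    def summary(self) -> str:
        lines = [
            "Signature exposure fit",
            f"  catalog size: {self.n_total}",
            f"  reconstruction cosine: {self.reconstruction_cosine:.4f}",
            f"  retained: {', '.join(self.retained)}",
            "",
            self.to_frame().to_string(index=False, float_format=lambda x: f"{x:.4f}"),
        ]
        return "\n".join(lines)


class SignatureModel:
    """Multinomial signature-mixture model for one 96-channel catalog."""

    def __init__(self, catalog: Catalog, reference: SignatureReference):
        if tuple(catalog.channels) != CHANNELS_96:
            raise ValueError("catalog must be a 96-channel catalog in canonical order")
        if catalog.n_total < 1:
            raise ValueError("empty catalog")
        if reference.n_signatures == 0:
            raise ValueError("empty signature reference")
        self.catalog = catalog
        self.reference = reference
        self.counts = np.asarray(catalog.counts, dtype=float)

    def fit(self, elimination_threshold: float | None = 0.01) -> SignatureFitResults:
        """Maximum-likelihood exposures with backward elimination.

        ``elimination_threshold=None`` disables elimination and returns
        the plain maximum-likelihood fit over all reference signatures.
        """
        names = list(self.reference.names)
        freq = self.counts / self.counts.sum()
        active = list(range(len(names)))
        P = self.reference.matrix
        w = _em(self.counts, P[:, active])
        cos = _cosine(P[:, active] @ w, freq)
        while elimination_threshold is not None and len(active) > 1:
            drop_pos = int(np.argmin(w))
            trial = active[:drop_pos] + active[drop_pos + 1 :]
            w_trial = _em(self.counts, P[:, trial])
            cos_trial = _cosine(P[:, trial] @ w_trial, freq)
            if cos - cos_trial < elimination_threshold:
                active, w, cos = trial, w_trial, cos_trial
            else:
                break
        proportions = np.zeros(len(names))
        proportions[active] = w
        return SignatureFitResults(
            model=self,
            signatures=tuple(names),
            proportions=proportions,
            retained=tuple(names[i] for i in active),
            reconstruction_cosine=cos,
            n_total=self.catalog.n_total,
        )


def fit_exposures(
    catalog: Catalog,
    reference: SignatureReference,
    elimination_threshold: float | None = 0.01,
) -> SignatureFitResults:
    """Fit signature exposures for a catalog (see :class:`SignatureModel`)."""
    return SignatureModel(catalog, reference).fit(elimination_threshold)


def bootstrap_ci(
    catalog: Catalog,
    reference: SignatureReference,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    elimination_threshold: float = 0.01,
) -> SignatureFitResults:
    """Fit exposures and attach multinomial-bootstrap percentile CIs."""
    return fit_exposures(catalog, reference, elimination_threshold).conf_int(
        n_boot=n_boot, seed=seed
    )


def nnls_exposures(catalog: Catalog, reference: SignatureReference) -> np.ndarray:
    """Non-negative least squares on channel frequencies.

    Provided as an alternative estimator and cross-check for the
    maximum-likelihood fit; returns normalised proportions over the full
    reference (no elimination).
    """
    from scipy.optimize import nnls

    freq = np.asarray(catalog.counts, dtype=float)
    freq = freq / freq.sum()
    w, _ = nnls(reference.matrix, freq)
    total = w.sum()
    return w / total if total > 0 else w


# ---------------------------------------------------------------------------
# Transcriptional strand bias
# ---------------------------------------------------------------------------


@dataclass
class StrandBiasResult:
    """Exact binomial test of transcribed vs untranscribed mutation counts."""

    signature: str
    transcribed_count: int
    untranscribed_count: int
    ratio: float
    p_value: float
    significant: bool


def strand_bias_test(
    transcribed_count: int,
    untranscribed_count: int,
    signature: str = "",
    alpha: float = 0.05,
) -> StrandBiasResult:
    """Two-sided exact binomial test of strand counts against p = 0.5.

    Transcription-coupled repair of adduct-forming mutagens (such as
    melphalan) leaves an asymmetry between the transcribed and
    untranscribed strands; a significant departure from 50:50 flags it.
    """
    t, u = int(transcribed_count), int(untranscribed_count)
    n = t + u
    if n < 1:
        raise ValueError("no stranded mutations")
    p = float(stats.binomtest(t, n, 0.5, alternative="two-sided").pvalue)
    ratio = t / u if u > 0 else np.inf
    return StrandBiasResult(
        signature=signature,
        transcribed_count=t,
        untranscribed_count=u,
        ratio=ratio,
        p_value=p,
        significant=p < alpha,
    )


def strand_bias_for_signature(
    mutations: list[MutationRecord],
    results: SignatureFitResults,
    signature: str,
    posterior_threshold: float = 0.5,
    alpha: float = 0.05,
) -> StrandBiasResult:
    """Strand-bias test on mutations attributed to one signature.

    A stranded mutation is attributed to ``signature`` when the fitted
    model's posterior probability for that signature, given the
    mutation's channel, is at least ``posterior_threshold``.
    """
    from .catalogs import CHANNEL_INDEX

    j = results.signatures.index(signature)
    post = results.posterior_channel_probabilities()[:, j]
    t = u = 0
    for m in mutations:
        if m.strand not in STRANDED:
            continue
        if post[CHANNEL_INDEX[m.context96]] >= posterior_threshold:
            if m.strand == "transcribed":
                t += 1
            else:
                u += 1
    if t + u == 0:
        raise ValueError(f"no stranded mutations attributed to {signature}")
    return strand_bias_test(t, u, signature=signature, alpha=alpha)


# ---------------------------------------------------------------------------
# Pooled chemotherapy contribution to nonsynonymous mutations
# ---------------------------------------------------------------------------


def nonsyn_chemo_fraction(
    catalogs: list[Catalog],
    reference: SignatureReference,
    chemo_signatures: tuple[str, ...] = ("SBS-MM1", "SBS35"),
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    elimination_threshold: float | None = None,
) -> tuple[float, tuple[float, float], pd.DataFrame]:
    """Pooled chemotherapy-signature fraction across patients, with CI.

    Nonsynonymous mutations are few per patient, so the per-patient
    catalogs (one per relapse-phase patient) are pooled into a single
    cohort catalog before fitting; the estimate is the summed SBS-MM1 +
    SBS35 exposure proportion of that pooled fit.  The bootstrap
    resamples every patient's catalog multinomially, re-pools and refits
    per replicate, preserving the per-patient sampling structure.
    Returns (estimate, (ci_low, ci_high), per-patient table).
    """
    if not catalogs:
        raise ValueError("no relapse-phase catalogs provided")
    rng = np.random.default_rng(seed)
    pooled_counts = np.sum([np.asarray(c.counts, float) for c in catalogs], axis=0)
    pooled = Catalog(CHANNELS_96, pooled_counts)
    pooled_fit = fit_exposures(pooled, reference, elimination_threshold)
    chemo_idx = [reference.names.index(s) for s in chemo_signatures]

    def chemo_proportion(fit: SignatureFitResults) -> float:
        return float(sum(fit.proportions[j] for j in chemo_idx))

    estimate = chemo_proportion(pooled_fit)

    M = np.zeros((96, n_boot))
    for c in catalogs:
        p_obs = np.asarray(c.counts, float) / c.n_total
        M += rng.multinomial(c.n_total, p_obs, size=n_boot).T
    keep = [pooled_fit.signatures.index(s) for s in pooled_fit.retained]
    W = _em_batch(M, reference.matrix[:, keep])
    boot = np.zeros(n_boot)
    for row, j in enumerate(keep):
        if j in chemo_idx:
            boot += W[row]
    lo, hi = np.percentile(boot, [2.5, 97.5])

    per_patient = [fit_exposures(c, reference, None) for c in catalogs]
    table = pd.DataFrame(
        {
            "n_nonsyn": [c.n_total for c in catalogs],
            "chemo_fraction": [chemo_proportion(f) for f in per_patient],
        }
    )
    return float(estimate), (float(lo), float(hi)), table
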