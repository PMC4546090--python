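"""Partially methylated domain (PMD) segmentation and PMD-based classification.

PMDs are megabase-scale blocks of intermediate CG methylation standing out
against a highly methylated background. Detection runs on a track of
nonoverlapping windows (10 kb by default): a two-state hidden Markov model
with Gaussian emissions on the window methylation level is fitted by EM
(Baum-Welch with a sticky Dirichlet prior on the transitions, emission
parameters initialised from a two-component Gaussian mixture) and decoded
by Viterbi. The state with the lower emission mean is the PMD state.
Consecutive PMD windows become segments; segments shorter than
``min_length`` are dropped, and a separate ``report_min_length`` mirrors
the convention of only reporting domains of at least 500 kb.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .io import GeneModel

MIN_INFORMATIVE_WINDOWS = 50


def _viterbi(x, means, variances, log_start, log_trans):
    """Viterbi path for a 2-state Gaussian HMM (log-space)."""
    ll = -0.5 * (
        np.log(2 * np.pi * variances)[None, :]
        + (x[:, None] - means[None, :]) ** 2 / variances[None, :]
    )
    n = len(x)
    delta = np.empty((n, 2))
    psi = np.zeros((n, 2), dtype=int)
    delta[0] = log_start + ll[0]
    for t in range(1, n):
        trans = delta[t - 1][:, None] + log_trans
        psi[t] = trans.argmax(axis=0)
        delta[t] = trans.max(axis=0) + ll[t]
    path = np.empty(n, dtype=int)
    path[-1] = delta[-1].argmax()
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _forward_backward(x, means, variances, log_start, log_trans):
    """Scaled forward-backward; returns state posteriors, pairwise transition
    expectations and the log-likelihood."""
    ll = -0.5 * (
        np.log(2 * np.pi * variances)[None, :]
        + (x[:, None] - means[None, :]) ** 2 / variances[None, :]
    )
    b = np.exp(ll - ll.max(axis=1, keepdims=True))
    trans = np.exp(log_trans)
    n = len(x)
    alpha = np.empty((n, 2))
    beta = np.empty((n, 2))
    scale = np.empty(n)
    alpha[0] = np.exp(log_start) * b[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ trans) * b[t]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (trans @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = np.zeros((2, 2))
    for t in range(n - 1):
        m = alpha[t][:, None] * trans * (b[t + 1] * beta[t + 1])[None, :] / scale[t + 1]
        xi += m
    loglik = np.log(scale).sum() + ll.max(axis=1).sum()
    return gamma, xi, loglik


class PMDSegmenter(BaseEstimator):
    """Two-state Gaussian HMM segmenter for partially methylated domains.

    Parameters
    ----------
    min_length : int
        Minimum segment length in bp retained internally (default 100 kb).
    report_min_length : int
        Length threshold applied by :meth:`segments` when ``report=True``
        (default 500 kb).
    self_transition_prior : float
        Pseudocount favouring staying in the same state; sets the sticky
        prior that keeps segments at the domain scale.
    min_state_separation : float
        Minimum difference between the two fitted emission means for PMD
        calls to be made at all; below it the track is considered
        homogeneous and no PMDs are reported.
    n_iter, tol : EM iteration controls.

    Attributes (after :meth:`fit`)
    ----------
    means_, variances_ : ndarray of shape (2,), sorted so state 0 is the
        PMD (lower-mean) state.
    transmat_ : ndarray of shape (2, 2) fitted transition matrix.
    converged_ : bool
    separation_ : float, difference between the state means.
    """

    def __init__(
        self,
        min_length: int = 100_000,
        report_min_length: int = 500_000,
        self_transition_prior: float = 10.0,
        min_state_separation: float = 0.1,
        n_iter: int = 100,
        tol: float = 1e-4,
        random_state: int = 0,
    ):
        self.min_length = min_length
        self.report_min_length = report_min_length
        self.self_transition_prior = self_transition_prior
        self.min_state_separation = min_state_separation
        self.n_iter = n_iter
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _sequences(track: pd.DataFrame):
        """Per-chromosome sequences of observed (non-missing) window levels."""
        out = []
        for chrom, sub in track.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            obs = sub.dropna(subset=["level"])
            if len(obs):
                out.append((chrom, obs))
        return out

    def fit(self, track: pd.DataFrame, y=None) -> "PMDSegmenter":
        """Fit emission and transition parameters on a window track
        (frame with chrom/start/end/level; missing levels are skipped)."""
        seqs = self._sequences(track)
        x_all = np.concatenate([s["level"].to_numpy() for _, s in seqs]) if seqs else np.array([])
        if len(x_all) < MIN_INFORMATIVE_WINDOWS:
            raise ValueError(
                f"need >= {MIN_INFORMATIVE_WINDOWS} informative windows to fit emissions, "
                f"got {len(x_all)}"
            )
        gmm = GaussianMixture(
            n_components=2, n_init=3, random_state=self.random_state, reg_covar=1e-4
        ).fit(x_all.reshape(-1, 1))
        order = np.argsort(gmm.means_.ravel())
        means = gmm.means_.ravel()[order]
        variances = np.maximum(gmm.covariances_.ravel()[order], 1e-4)
        trans = np.array([[0.99, 0.01], [0.01, 0.99]])
        start = np.array([0.5, 0.5])
        prior = self.self_transition_prior * np.eye(2)

        prev = -np.inf
        self.converged_ = False
        for _ in range(self.n_iter):
            g_sum = np.zeros(2)
            gx = np.zeros(2)
            gx2 = np.zeros(2)
            xi_sum = np.zeros((2, 2))
            start_sum = np.zeros(2)
            total_ll = 0.0
            for _, sub in seqs:
                x = sub["level"].to_numpy()
                gamma, xi, ll = _forward_backward(
                    x, means, variances, np.log(start), np.log(trans)
                )
                g_sum += gamma.sum(axis=0)
                gx += gamma.T @ x
                gx2 += gamma.T @ (x * x)
                xi_sum += xi
                start_sum += gamma[0]
                total_ll += ll
            means = gx / g_sum
            variances = np.maximum(gx2 / g_sum - means**2, 1e-5)
            trans = xi_sum + prior
            trans /= trans.sum(axis=1, keepdims=True)
            start = (start_sum + 1.0) / (start_sum + 1.0).sum()
            if abs(total_ll - prev) < self.tol:
                self.converged_ = True
                break
            prev = total_ll
        order = np.argsort(means)
        self.means_ = means[order]
        self.variances_ = variances[order]
        self.transmat_ = trans[np.ix_(order, order)]
        self.startprob_ = start[order]
        self.separation_ = float(self.means_[1] - self.means_[0])
        return self

    def predict(self, track: pd.DataFrame) -> pd.Series:
        """Viterbi state labels ('PMD'/'background') per track row; missing
        windows get no label (NA)."""
        check_is_fitted(self, "means_")
        labels = pd.Series(pd.NA, index=track.index, dtype="object")
        if self.separation_ < self.min_state_separation:
            obs = track["level"].notna()
            labels[obs] = "background"
            return labels
        for _, sub in self._sequences(track):
            path = _viterbi(
                sub["level"].to_numpy(),
                self.means_,
                self.variances_,
                np.log(self.startprob_),
                np.log(self.transmat_),
            )
            labels.loc[sub.index] = np.where(path == 0, "PMD", "background")
        return labels

    def segments(self, track: pd.DataFrame, report: bool = False) -> pd.DataFrame:
        """Merge consecutive PMD-state windows into segments.

        Interior windows with missing levels are bridged (a missing window
        between two PMD windows does not break the segment). Segments
        shorter than ``min_length`` are dropped; with ``report=True`` the
        ``report_min_length`` filter is applied instead.
        """
        labels = self.predict(track)
        segs: list[dict] = []
        for chrom, sub in track.assign(pmd_label=labels).groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            obs = sub[sub["pmd_label"].notna()]
            cur = None
            for row in obs.itertuples():
                if row.pmd_label == "PMD":
                    if cur is None:
                        cur = {"chrom": chrom, "start": row.start, "end": row.end,
                               "levels": [row.level], "n_windows": 1}
                    else:
                        cur["end"] = row.end
                        cur["levels"].append(row.level)
                        cur["n_windows"] += 1
                elif cur is not None:
                    segs.append(cur)
                    cur = None
            if cur is not None:
                segs.append(cur)
        min_len = self.report_min_length if report else self.min_length
        rows = [
            {
                "chrom": s["chrom"],
                "start": int(s["start"]),
                "end": int(s["end"]),
                "mean_level": float(np.mean(s["levels"])),
                "n_windows": s["n_windows"],
            }
            for s in segs
            if s["end"] - s["start"] >= min_len
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_level", "n_windows"])


def segment_pmds(
    window_track: pd.DataFrame,
    min_length: int = 100_000,
    report_min_length: int = 500_000,
    report: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """Fit a :class:`PMDSegmenter` on a window track and return its segments."""
    seg = PMDSegmenter(
        min_length=min_length, report_min_length=report_min_length, **kwargs
    ).fit(window_track)
    return seg.segments(window_track, report=report)


def classify_windows_pmd(windows: pd.DataFrame, pmds: pd.DataFrame) -> pd.Series:
    """Label every window 'PMD' if it overlaps any PMD segment by >= 1 bp,
    else 'non-PMD' (half-open intervals: an abutting window does not overlap)."""
    labels = np.full(len(windows), "non-PMD", dtype=object)
    for chrom, seg in pmds.groupby("chrom"):
        mask = windows["chrom"].to_numpy() == chrom
        if not mask.any():
            continue
        ws = windows.loc[mask, "start"].to_numpy()
        we = windows.loc[mask, "end"].to_numpy()
        hit = np.zeros(mask.sum(), dtype=bool)
        for s in seg.itertuples():
            hit |= (ws < s.end) & (s.start < we)
        labels[np.flatnonzero(mask)[hit]] = "PMD"
    return pd.Series(labels, index=windows.index, name="pmd_status")


def promoter_interval(
    gene: GeneModel, upstream: int = 2000, downstream: int = 500
) -> tuple[int, int]:
    """Strand-aware promoter window around the TSS, clipped at 0.

    [tss - upstream, tss + downstream) on '+', [tss - downstream, tss + upstream) on '-'.
    """
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    return max(start, 0), max(end, 0)


def assign_pmd_genes(
    genes: list[GeneModel],
    pmds: pd.DataFrame,
    upstream: int = 2000,
    downstream: int = 500,
) -> pd.Series:
    """Label genes whose promoter (2 kb upstream to 500 bp downstream of the
    TSS, strand-aware) overlaps any PMD as 'PMD gene', the rest 'non-PMD gene'."""
    labels = {}
    by_chrom = {c: g for c, g in pmds.groupby("chrom")}
    for gene in genes:
        ps, pe = promoter_interval(gene, upstream, downstream)
        seg = by_chrom.get(gene.chrom)
        hit = False
        if seg is not None:
            hit = bool(((seg["start"] < pe) & (ps < seg["end"])).any())
        labels[gene.id] = "PMD gene" if hit else "non-PMD gene"
    return pd.Series(labels, name="pmd_gene")


def pmd_expression_summary(labels: pd.Series, expression: pd.DataFrame) -> dict:
    """log2(FPKM + 1) distributions of PMD vs non-PMD genes, with medians.

    ``labels`` is the output of :func:`assign_pmd_genes`; every labelled
    gene must be present in the expression table (rows = genes, columns =
    stages).
    """
    missing = set(labels.index) - set(expression.index)
    if missing:
        raise KeyError(f"genes missing from expression table: {sorted(missing)[:5]}")
    log_expr = np.log2(expression.loc[labels.index] + 1.0)
    pmd = log_expr[labels == "PMD gene"]
    non = log_expr[labels == "non-PMD gene"]
    return {
        "pmd": pmd,
        "non_pmd": non,
        "pmd_median": pmd.stack().median() if len(pmd) else float("nan"),
        "non_pmd_median": non.stack().median() if len(non) else float("nan"),
    }
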