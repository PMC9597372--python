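"""Bipartite regulatory-network inference with a Bernoulli latent block model.

The incidence matrix links TF families (rows) to target genes (columns):
entry (f, g) is 1 when at least one tPLM assigned to family f occurs in
gene g's proximal region.  The latent block model (LBM) co-clusters rows
and columns: each row belongs to one of Q row modules, each column to one
of L column modules, and an edge appears with a module-pair probability
pi[q, l].  Fitting uses variational EM with a fully factorised posterior
(mean-field): E-steps are coordinate ascent on row and column membership
posteriors, M-steps re-estimate pi and the mixing proportions from
posterior-weighted block means, so the variational bound never decreases.
Model dimensions are selected by the integrated completed likelihood
(ICL): the completed log-likelihood at the hard assignments minus the
usual BIC-style penalties for the block parameters and the two mixture
proportion vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

PROB_FLOOR = 1e-9
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500
DEFAULT_N_STARTS = 20


@dataclass
class BipartiteIncidence:
    """Binary TF-family x target-gene matrix with labels."""

    row_labels: list[str]
    col_labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")

    @property
    def zero_rows(self) -> list[str]:
        return [r for r, s in zip(self.row_labels, self.matrix.sum(axis=1)) if s == 0]

    @property
    def zero_cols(self) -> list[str]:
        return [c for c, s in zip(self.col_labels, self.matrix.sum(axis=0)) if s == 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.row_labels,
                            columns=self.col_labels)


def build_incidence(annotations, plms, target_genes) -> BipartiteIncidence:
    """Incidence from tPLM evidence: (family, gene) = 1 iff some tPLM of
    that family has the gene in its containing-gene set.

    ``annotations`` maps motif -> PLMAnnotation (for TF family labels),
    ``plms`` supplies the per-motif gene sets.
    """
    target_genes = list(target_genes)
    gene_index = {g: j for j, g in enumerate(target_genes)}
    families: list[str] = []
    links: set[tuple[str, str]] = set()
    for p in plms:
        ann = annotations.get(p.motif)
        if ann is None or ann.assignment not in ("tPLM", "both"):
            continue
        fams = {m["family"] for m in ann.tf_matches if m["family"]}
        for fam in fams:
            if fam not in families:
                families.append(fam)
            for g in p.gene_set:
                if g in gene_index:
                    links.add((fam, g))
    families.sort()
    matrix = np.zeros((len(families), len(target_genes)), dtype=np.int8)
    fam_index = {f: i for i, f in enumerate(families)}
    for fam, g in links:
        matrix[fam_index[fam], gene_index[g]] = 1
    return BipartiteIncidence(row_labels=families, col_labels=target_genes,
                              matrix=matrix)


@dataclass
class LBMFit:
    Q_rows: int
    Q_cols: int
    row_posteriors: np.ndarray  # n x Q
    col_posteriors: np.ndarray  # d x L
    pi: np.ndarray              # Q x L block connection probabilities
    row_proportions: np.ndarray
    col_proportions: np.ndarray
    bound_trace: list[float]
    icl: float
    seed: int
    n_starts: int
    start_index: int

    @property
    def bound(self) -> float:
        return self.bound_trace[-1]

    @property
    def row_assignments(self) -> np.ndarray:
        return self.row_posteriors.argmax(axis=1)

    @property
    def col_assignments(self) -> np.ndarray:
        return self.col_posteriors.argmax(axis=1)


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)


def _normalize_rows_log(logp: np.ndarray) -> np.ndarray:
    return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))


def _bound(X, tau, rho, pi, alpha, beta) -> float:
    """Mean-field evidence lower bound for the Bernoulli LBM."""
    lpi, lmi = np.log(pi), np.log1p(-pi)
    ll = float(np.einsum("iq,jl,ij,ql->", tau, rho, X, lpi)
               + np.einsum("iq,jl,ij,ql->", tau, rho, 1 - X, lmi))
    ll += float((tau * np.log(alpha)).sum())
    ll += float((rho * np.log(beta)).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(tau * np.log(np.where(tau > 0, tau, 1.0)))
        ent -= np.nansum(rho * np.log(np.where(rho > 0, rho, 1.0)))
    return ll + float(ent)


def _hard_init(size: int, k: int, rng) -> np.ndarray:
    """Near-one-hot posteriors from a random partition with all k groups used."""
    labels = rng.integers(k, size=size)
    labels[rng.permutation(size)[:k]] = np.arange(k)  # no empty group
    post = np.full((size, k), 0.05 / max(k - 1, 1))
    post[np.arange(size), labels] = 0.95
    return post / post.sum(axis=1, keepdims=True)


def _soften(labels: np.ndarray, k: int) -> np.ndarray:
    post = np.full((labels.size, k), 0.05 / max(k - 1, 1))
    post[np.arange(labels.size), labels] = 0.95
    return post / post.sum(axis=1, keepdims=True)


def _kmeans_init(X, Q, L, rng):
    """Cluster rows and columns of the incidence independently (k-means)."""
    from sklearn.cluster import KMeans

    state = int(rng.integers(2 ** 31 - 1))
    z = KMeans(n_clusters=Q, n_init=4, random_state=state).fit_predict(X)
    w = KMeans(n_clusters=L, n_init=4, random_state=state).fit_predict(X.T)
    return _soften(z, Q), _soften(w, L)


def _vem_once(X, Q, L, rng, tol, max_iter, init="random"):
    n, d = X.shape
    if init == "kmeans":
        tau, rho = _kmeans_init(X, Q, L, rng)
    else:
        tau = _hard_init(n, Q, rng)
        rho = _hard_init(d, L, rng)
    trace: list[float] = []
    pi = alpha = beta = None
    for _ in range(max_iter):
        # M-step: block means weighted by the current posteriors
        weight = tau.sum(axis=0)[:, None] * rho.sum(axis=0)[None, :]
        pi = _clamp((tau.T @ X @ rho) / np.maximum(weight, PROB_FLOOR))
        alpha = _clamp(tau.mean(axis=0))
        alpha = alpha / alpha.sum()
        beta = _clamp(rho.mean(axis=0))
        beta = beta / beta.sum()
        # E-step: coordinate ascent on tau then rho
        lpi, lmi = np.log(pi), np.log1p(-pi)
        log_tau = np.log(alpha)[None, :] + (X @ rho) @ lpi.T + ((1 - X) @ rho) @ lmi.T
        tau = _normalize_rows_log(log_tau)
        log_rho = np.log(beta)[None, :] + (X.T @ tau) @ lpi + ((1 - X.T) @ tau) @ lmi
        rho = _normalize_rows_log(log_rho)
        trace.append(_bound(X, tau, rho, pi, alpha, beta))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
    return tau, rho, pi, alpha, beta, trace


def _icl(X, tau, rho, pi, alpha, beta) -> float:
    """Integrated completed likelihood at the hard (max-posterior) assignments."""
    n, d = X.shape
    Q, L = pi.shape
    z = tau.argmax(axis=1)
    w = rho.argmax(axis=1)
    lpi, lmi = np.log(pi), np.log1p(-pi)
    block = pi[np.ix_(z, w)]
    ll = float((X * np.log(block) + (1 - X) * np.log1p(-block)).sum())
    ll += float(np.log(alpha)[z].sum() + np.log(beta)[w].sum())
    penalty = ((Q - 1) / 2 * np.log(n) + (L - 1) / 2 * np.log(d)
               + Q * L / 2 * np.log(n * d))
    return ll - penalty


def lbm_vem_fit(
    matrix,
    Q_rows: int,
    Q_cols: int,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> LBMFit:
    """Fit a Bernoulli LBM by variational EM, keeping the best of n_starts.

    Restarts are seeded deterministically from ``seed``; ties on the
    final bound go to the lowest start index.
    """
    if isinstance(matrix, BipartiteIncidence):
        matrix = matrix.matrix
    X = np.asarray(matrix, dtype=float)
    if X.size == 0:
        raise ValueError("empty incidence matrix")
    if not (1 <= Q_rows <= X.shape[0] and 1 <= Q_cols <= X.shape[1]):
        raise ValueError("module counts must be within matrix dimensions")
    best = None
    for s in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), s]))
        tau, rho, pi, alpha, beta, trace = _vem_once(
            X, Q_rows, Q_cols, rng, tol, max_iter,
            init="kmeans" if s == 0 else "random",
        )
        if best is None or trace[-1] > best[-1][-1]:
            best = (s, tau, rho, pi, alpha, beta, trace)
    s, tau, rho, pi, alpha, beta, trace = best
    return LBMFit(
        Q_rows=Q_rows, Q_cols=Q_cols, row_posteriors=tau, col_posteriors=rho,
        pi=pi, row_proportions=alpha, col_proportions=beta,
        bound_trace=trace, icl=_icl(X, tau, rho, pi, alpha, beta),
        seed=int(seed), n_starts=n_starts, start_index=s,
    )


def icl_select(
    matrix,
    Q_rows_range,
    Q_cols_range,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
) -> LBMFit:
    """Fit every (Q, L) pair in the ranges and return the ICL-maximising fit."""
    best = None
    for Q in Q_rows_range:
        for L in Q_cols_range:
            fit = lbm_vem_fit(matrix, Q, L, n_starts=n_starts, seed=seed)
            if best is None or fit.icl > best.icl:
                best = fit
    if best is None:
        raise ValueError("empty model range")
    return best


def describe_modules(fit: LBMFit, incidence: BipartiteIncidence) -> dict:
    """Per-module member lists, fitted vs observed block densities.

    Fitted module indices that attract no member (possible when the
    posterior collapses) are reported with empty lists.
    """
    import logging

    X = incidence.matrix
    z, w = fit.row_assignments, fit.col_assignments
    row_modules = {q: [incidence.row_labels[i] for i in np.nonzero(z == q)[0]]
                   for q in range(fit.Q_rows)}
    col_modules = {l: [incidence.col_labels[j] for j in np.nonzero(w == l)[0]]
                   for l in range(fit.Q_cols)}
    for q, members in row_modules.items():
        if not members:
            logging.getLogger(__name__).warning("row module %d is empty", q)
    for l, members in col_modules.items():
        if not members:
            logging.getLogger(__name__).warning("column module %d is empty", l)
    blocks = []
    for q in range(fit.Q_rows):
        for l in range(fit.Q_cols):
            sub = X[np.ix_(z == q, w == l)]
            blocks.append({
                "row_module": q, "col_module": l,
                "pi_hat": float(fit.pi[q, l]),
                "observed_density": float(sub.mean()) if sub.size else float("nan"),
                "n_rows": int((z == q).sum()), "n_cols": int((w == l).sum()),
            })
    return {"row_modules": row_modules, "col_modules": col_modules,
            "blocks": pd.DataFrame(blocks)}
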