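"""Non-metric multidimensional scaling and LDA-based species assignment.

COI cannot separate the recently radiated Delphininae (Delphinus delphis,
Stenella coeruleoalba, Stenella frontalis), so control-region distances are
embedded with non-metric MDS and species are assigned by linear discriminant
analysis on the embedding coordinates.  References and queries are embedded
jointly in a single nMDS; the LDA is then fitted on the reference points only
and produces posterior probabilities for every point (self-classification for
references, assignment for queries).

The nMDS is Kruskal's: it seeks coordinates whose inter-point distances
reproduce the *rank order* of the input distances, minimizing stress-1

    sqrt( sum (dhat_ij - d_ij)^2 / sum d_ij^2 )

where dhat are the disparities obtained by isotonic (monotone) regression of
the embedded distances on the input-distance ranks.  Optimization is SMACOF
(majorization via the Guttman transform) alternated with the isotonic fit;
ties in the input distances are handled by Kruskal's primary (weak) approach.
Multiple restarts are used; the first is initialized from classical scaling
(PCoA), the rest at random from the given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .distances import DistanceMatrix, distance_matrix
from .seqio import UNDETERMINED, AlignedSeqSet


@dataclass
class OrdinationResult:
    labels: list[str]
    coordinates: np.ndarray  # (n, k), centered at the origin
    stress: float  # Kruskal stress-1 of the best restart
    stress_trace: list[float]  # per-iteration stress-1 of the best restart
    n_restarts_used: int
    converged: bool
    seed: int | None

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]


def _classical_scaling_init(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling (PCoA) coordinates as a warm start."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    L = np.sqrt(np.clip(vals[order], 0.0, None))
    return vecs[:, order] * L


def _smacof_single(
    delta: np.ndarray, X0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float], bool]:
    """One nMDS run: returns (coords, stress-1, stress trace, converged).

    ``delta`` is the condensed input-distance vector; ties are handled by the
    primary approach (within a tie block the disparities are free to follow
    the embedded distances).
    """
    n = X0.shape[0]
    m = delta.shape[0]
    X = X0 - X0.mean(axis=0)
    trace: list[float] = []
    converged = False
    prev = np.inf
    for _ in range(max_iter):
        dist = pdist(X)
        # primary tie approach: sort by (input distance, embedded distance)
        perm = np.lexsort((dist, delta))
        disp = np.empty(m)
        disp[perm] = isotonic_regression(dist[perm]).x
        denom = (dist**2).sum()
        stress = (
            math.sqrt(((disp - dist) ** 2).sum() / denom) if denom > 0 else 1.0
        )
        trace.append(stress)
        if prev - stress < tol:
            converged = prev - stress > -tol  # flat, not diverging
            break
        prev = stress
        # Guttman majorization step.  The disparities are rescaled to a fixed
        # norm to stop the configuration shrinking; stress-1 is invariant to
        # that uniform rescaling, so the trace above is unaffected.
        ssq = (disp**2).sum()
        if ssq <= 0:
            break
        disp_s = disp * math.sqrt(m / ssq)
        dmat = squareform(dist)
        ratio = np.zeros_like(dmat)
        nz = dmat > 0
        ratio[nz] = squareform(disp_s)[nz] / dmat[nz]
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = (B @ X) / n
        X -= X.mean(axis=0)
    return X, trace[-1] if trace else 1.0, trace, converged


def nmds(
    m: DistanceMatrix | np.ndarray,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 500,
    seed: int | None = None,
    tol: float = 1e-9,
) -> OrdinationResult:
    """Kruskal nMDS of a distance matrix into ``k`` dimensions.

    Runs ``n_restarts`` optimizations (classical-scaling start first, then
    random starts from ``seed``) and keeps the lowest-stress configuration.
    Requires n >= k + 2 and a fully defined matrix.
    """
    if isinstance(m, DistanceMatrix):
        if m.undefined_pairs():
            raise ValueError(
                f"UNDEFINED distances present: {m.undefined_pairs()[:5]} ..."
            )
        labels = list(m.labels)
        D = m.d.astype(float)
    else:
        D = np.asarray(m, dtype=float)
        labels = [str(i) for i in range(D.shape[0])]
    n = D.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} points for a {k}-D embedding")
    delta = squareform(D, checks=False)
    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for r in range(max(1, n_restarts)):
        if r == 0:
            X0 = _classical_scaling_init(D, k)
            if not np.isfinite(X0).all() or np.allclose(X0, 0):
                X0 = rng.standard_normal((n, k))
        else:
            X0 = rng.standard_normal((n, k))
        X, stress, trace, conv = _smacof_single(delta, X0, max_iter, tol)
        any_converged = any_converged or conv
        if best is None or stress < best[1]:
            best = (X, stress, trace, conv)
    X, stress, trace, _ = best
    return OrdinationResult(
        labels, X - X.mean(axis=0), stress, trace,
        max(1, n_restarts), any_converged, seed
    )


@dataclass
class LdaAssignment:
    query_id: str
    posteriors: dict[str, float]
    called_species: str
    is_reference: bool
    training_accuracy: float


class _GaussianLda:
    """Gaussian LDA with pooled within-class covariance and equal priors."""

    def __init__(self, ridge: float = 1e-8) -> None:
        self.ridge = ridge
        self.jittered = False

    def fit(self, X: np.ndarray, y: list[str]) -> "_GaussianLda":
        self.classes_ = sorted(set(y))
        if len(self.classes_) < 2:
            raise ValueError("LDA needs at least 2 reference species")
        k = X.shape[1]
        self.means_ = {}
        pooled = np.zeros((k, k))
        dof = 0
        for c in self.classes_:
            Xc = X[[i for i, lab in enumerate(y) if lab == c]]
            if Xc.shape[0] < 2:
                raise ValueError(f"species {c!r} needs >= 2 reference points")
            mu = Xc.mean(axis=0)
            self.means_[c] = mu
            pooled += (Xc - mu).T @ (Xc - mu)
            dof += Xc.shape[0] - 1
        pooled /= dof
        if np.linalg.matrix_rank(pooled) < k or np.linalg.cond(pooled) > 1e12:
            pooled = pooled + self.ridge * np.eye(k)
            self.jittered = True
        self.prec_ = np.linalg.inv(pooled)
        return self

    def log_posteriors(self, X: np.ndarray) -> np.ndarray:
        scores = np.empty((X.shape[0], len(self.classes_)))
        for j, c in enumerate(self.classes_):
            mu = self.means_[c]
            scores[:, j] = X @ self.prec_ @ mu - 0.5 * mu @ self.prec_ @ mu
        scores -= scores.max(axis=1, keepdims=True)
        log_norm = np.log(np.exp(scores).sum(axis=1, keepdims=True))
        return scores - log_norm


def lda_fit_assign(
    o: OrdinationResult,
    reference_labels: dict[str, str],
    query_ids: list[str] | None = None,
    ridge: float = 1e-8,
) -> list[LdaAssignment]:
    """Fit an equal-prior Gaussian LDA on the reference coordinates of a joint
    embedding and return posterior assignments for references and queries.

    ``reference_labels`` maps reference point label -> species.  Points of
    the ordination absent from that map are treated as queries (``query_ids``
    may restrict/reorder them).
    """
    idx = {lab: i for i, lab in enumerate(o.labels)}
    ref_ids = [lab for lab in o.labels if lab in reference_labels]
    if query_ids is None:
        query_ids = [lab for lab in o.labels if lab not in reference_labels]
    X_ref = o.coordinates[[idx[i] for i in ref_ids]]
    y_ref = [reference_labels[i] for i in ref_ids]
    lda = _GaussianLda(ridge).fit(X_ref, y_ref)

    def assignments(ids: list[str], is_ref: bool, accuracy: float
                    ) -> list[LdaAssignment]:
        X = o.coordinates[[idx[i] for i in ids]]
        logp = lda.log_posteriors(X)
        out = []
        for row, point_id in zip(np.exp(logp), ids):
            posts = dict(zip(lda.classes_, row.tolist()))
            called = lda.classes_[int(np.argmax(row))]
            out.append(LdaAssignment(point_id, posts, called, is_ref, accuracy))
        return out

    ref_post = lda.log_posteriors(X_ref)
    ref_calls = [lda.classes_[int(i)] for i in np.argmax(ref_post, axis=1)]
    accuracy = float(np.mean([c == t for c, t in zip(ref_calls, y_ref)]))
    return assignments(ref_ids, True, accuracy) + assignments(
        list(query_ids), False, accuracy
    )


@dataclass
class DelphininaeReport:
    stress: float
    converged: bool
    training_accuracy: float
    reference_assignments: list[LdaAssignment]
    query_assignments: list[LdaAssignment]
    seed: int | None
    lda_priors: str = "equal"

    def calls(self) -> dict[str, str]:
        return {a.query_id: a.called_species for a in self.query_assignments}


def assign_delphininae(
    reference: AlignedSeqSet,
    queries: AlignedSeqSet | None = None,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 500,
    seed: int | None = None,
) -> DelphininaeReport:
    """Full assignment pipeline for a low-divergence species complex:
    joint K2P distance matrix -> nMDS -> LDA posteriors.

    References must carry species labels; queries (optional) are embedded
    jointly but excluded from the LDA fit.
    """
    merged = reference.concat(queries) if queries is not None else reference
    dm = distance_matrix(merged)
    orde = nmds(dm, k=k, n_restarts=n_restarts, max_iter=max_iter, seed=seed)
    ref_labels = {
        sp.id: sp.species
        for sp in reference.specimens
        if sp.species != UNDETERMINED
    }
    query_ids = [sp.id for sp in (queries.specimens if queries else [])]
    assignments = lda_fit_assign(orde, ref_labels, query_ids)
    refs = [a for a in assignments if a.is_reference]
    qs = [a for a in assignments if not a.is_reference]
    acc = refs[0].training_accuracy if refs else float("nan")
    return DelphininaeReport(
        orde.stress, orde.converged, acc, refs, qs, seed
    )
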