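"""Duplication signatures by nonnegative matrix factorization.

Region features are aggregated into nonoverlapping genomic windows (10 Mbp
by default; a region contributes to every window it overlaps), four
magnitude-like features (length, G/C inside and at flanks, sequence
identity) are first binned into below-/above-mean indicator pairs, columns
are min-max scaled, and the resulting windows x features matrix A is
factorized as A ~ W H with all entries nonnegative.  H's rows are the
*signatures* — characteristic feature patterns of distinct duplication
processes; W carries their per-window loads.  The factorization minimizes
generalized Kullback-Leibler divergence via the classic multiplicative
updates, whose loss is provably nonincreasing.

Rank selection reports two diagnostics: the Fogel-Young volume (determinant
of the correlation matrix of H's rows — near zero when signatures are
redundant) and cross-restart stability (mean cosine similarity of optimally
matched signatures).  Individual regions are assigned to a signature by
nonnegative least squares of their (identically encoded) feature vector on
the signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls

__all__ = [
    "BINNED_FEATURES",
    "WindowMatrix",
    "build_window_matrix",
    "nmf_kl",
    "select_k",
    "SignatureModel",
    "fit_signatures",
    "encode_region_vectors",
    "assign_signatures",
    "chromosome_zone",
]

_EPS = 1e-12

# features replaced by below-/above-mean indicator pairs before summation
BINNED_FEATURES = ("length", "gc_inside", "gc_flank", "identity")


@dataclass
class WindowMatrix:
    """Scaled window-level matrix plus the encoding needed to reuse it."""

    A: pd.DataFrame  # windows x encoded features, min-max scaled
    bin_means: dict  # feature -> mean used for below/above binning
    col_min: pd.Series
    col_range: pd.Series
    dropped_windows: list = field(default_factory=list)


def _encode_binned(df: pd.DataFrame, binned, bin_means=None) -> tuple[pd.DataFrame, dict]:
    """Replace each binned feature by below-/above-mean indicator columns."""
    out = df.copy()
    means = {}
    for feat in binned:
        if feat not in out.columns:
            continue
        mean = bin_means[feat] if bin_means else float(out[feat].mean())
        means[feat] = mean
        out[f"{feat}_below"] = (out[feat] <= mean).astype(float)
        out[f"{feat}_above"] = (out[feat] > mean).astype(float)
        out = out.drop(columns=[feat])
    return out, means


def build_window_matrix(
    regions,
    features: pd.DataFrame,
    chrom_sizes: dict,
    window_bp: int = 10_000_000,
    binned_features=BINNED_FEATURES,
) -> WindowMatrix:
    """Sum encoded region features into nonoverlapping genomic windows.

    ``features`` is indexed by region id.  A region contributes its full
    encoded vector to every window it overlaps.  All-zero windows are
    dropped (recorded in ``dropped_windows``); columns are min-max scaled
    to [0, 1] and the scaling parameters retained so region-level vectors
    can be encoded identically later.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    encoded, means = _encode_binned(features, binned_features)
    encoded = encoded.select_dtypes(include=[np.number]).astype(float)
    if (encoded.to_numpy() < 0).any():
        raise ValueError("features must be nonnegative for NMF aggregation")

    windows = []
    index = []
    for chrom, size in chrom_sizes.items():
        for w in range(int(np.ceil(size / window_bp))):
            windows.append((chrom, w * window_bp, min((w + 1) * window_bp, size)))
            index.append(f"{chrom}:{w * window_bp}-{min((w + 1) * window_bp, size)}")
    A = pd.DataFrame(0.0, index=index, columns=encoded.columns)
    win_by_chrom: dict[str, list[int]] = {}
    for i, (chrom, _s, _e) in enumerate(windows):
        win_by_chrom.setdefault(chrom, []).append(i)
    for reg in regions:
        if reg.id not in encoded.index:
            continue
        vec = encoded.loc[reg.id]
        for wi in win_by_chrom.get(reg.chrom, ()):
            _c, ws, we = windows[wi]
            if reg.start < we and reg.end > ws:
                A.iloc[wi] += vec

    nonzero = A.sum(axis=1) > 0
    dropped = A.index[~nonzero].tolist()
    A = A.loc[nonzero]
    col_min = A.min()
    col_range = (A.max() - col_min).replace(0, 1.0)
    A = (A - col_min) / col_range
    return WindowMatrix(A=A, bin_means=means, col_min=col_min, col_range=col_range, dropped_windows=dropped)


def _kl_loss(A: np.ndarray, WH: np.ndarray) -> float:
    mask = A > 0
    return float(
        (A[mask] * np.log(A[mask] / np.maximum(WH[mask], _EPS))).sum()
        - A.sum()
        + WH.sum()
    )


def nmf_kl(
    A,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """KL-divergence NMF by multiplicative updates.

    Returns (W, H, loss trace).  Stops at ``max_iter`` or when the relative
    loss change drops below ``tol``.  The generalized KL divergence
    D(A || WH) is nonincreasing under these updates.
    """
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("A must be nonnegative")
    if k < 1:
        raise ValueError("k must be >= 1")
    n, f = A.shape
    rng = np.random.default_rng(seed)
    scale = max(A.mean(), _EPS) / k
    W = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, f))

    trace: list[float] = []
    prev = None
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        W *= (A / WH) @ H.T / np.maximum(H.sum(axis=1), _EPS)
        WH = np.maximum(W @ H, _EPS)
        H *= W.T @ (A / WH) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        loss = _kl_loss(A, np.maximum(W @ H, _EPS))
        trace.append(loss)
        if prev is not None and abs(prev - loss) <= tol * max(abs(prev), _EPS):
            break
        prev = loss
    return W, H, trace


def _match_cosine(H1: np.ndarray, H2: np.ndarray) -> float:
    """Mean cosine similarity under optimal one-to-one signature matching."""
    n1 = H1 / np.maximum(np.linalg.norm(H1, axis=1, keepdims=True), _EPS)
    n2 = H2 / np.maximum(np.linalg.norm(H2, axis=1, keepdims=True), _EPS)
    sim = n1 @ n2.T
    r, c = linear_sum_assignment(-sim)
    return float(sim[r, c].mean())


def fyv_score(H: np.ndarray) -> float:
    """Fogel-Young volume: determinant of the cosine-similarity matrix of
    H's rows (the Gram matrix of the unit-normalized signatures).

    Near-duplicate signatures make the matrix singular and the score ~0;
    mutually orthogonal signatures push it toward 1.  The Gram form is used
    rather than Pearson correlation so constant signatures stay well
    defined.
    """
    Hn = H / np.maximum(np.linalg.norm(H, axis=1, keepdims=True), _EPS)
    gram = Hn @ Hn.T
    return float(abs(np.linalg.det(gram)))


def select_k(
    A,
    k_range=range(2, 7),
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 300,
) -> pd.DataFrame:
    """FYV and stability diagnostics per candidate rank.

    Stability is the mean matched cosine similarity of signatures over all
    restart pairs; FYV is reported for the best-loss restart.  The table is
    diagnostic — no rank is auto-selected.
    """
    if n_restarts < 2:
        raise ValueError("n_restarts must be >= 2 for stability")
    A = np.asarray(A, dtype=float)
    rows = []
    for k in k_range:
        runs = []
        for r in range(n_restarts):
            W, H, trace = nmf_kl(A, k, max_iter=max_iter, seed=seed + 104_729 * r + k)
            if (H.sum(axis=1) < _EPS).any():
                continue  # degenerate restart: an empty signature
            runs.append((trace[-1], H))
        if len(runs) < 2:
            rows.append({"k": k, "fyv": np.nan, "stability": np.nan, "n_valid_restarts": len(runs)})
            continue
        best_H = min(runs, key=lambda t: t[0])[1]
        sims = [
            _match_cosine(runs[i][1], runs[j][1])
            for i in range(len(runs))
            for j in range(i + 1, len(runs))
        ]
        rows.append(
            {
                "k": k,
                "fyv": fyv_score(best_H),
                "stability": float(np.mean(sims)),
                "n_valid_restarts": len(runs),
            }
        )
    return pd.DataFrame(rows).set_index("k")


@dataclass
class SignatureModel:
    """Fitted factor pair with the encoding used to build A."""

    W: np.ndarray
    H: np.ndarray
    k: int
    loss_trace: list
    feature_names: list
    window_matrix: WindowMatrix


def fit_signatures(
    wm: WindowMatrix, k: int, n_restarts: int = 10, seed: int = 0, max_iter: int = 500
) -> SignatureModel:
    """Factorize a window matrix at rank k, keeping the best-loss restart."""
    best = None
    for r in range(n_restarts):
        W, H, trace = nmf_kl(wm.A.to_numpy(), k, max_iter=max_iter, seed=seed + 7919 * r)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace)
    W, H, trace = best
    return SignatureModel(
        W=W, H=H, k=k, loss_trace=trace, feature_names=list(wm.A.columns), window_matrix=wm
    )


def encode_region_vectors(
    features: pd.DataFrame, wm: WindowMatrix, binned_features=BINNED_FEATURES
) -> pd.DataFrame:
    """Encode per-region features exactly as the window matrix columns.

    Binning uses the window-fit means; scaling reuses the column min/range
    so a region vector lives in the same space as A's rows.
    """
    encoded, _ = _encode_binned(features, binned_features, bin_means=wm.bin_means)
    encoded = encoded.select_dtypes(include=[np.number]).astype(float)
    encoded = encoded.reindex(columns=wm.A.columns, fill_value=0.0)
    return (encoded - wm.col_min) / wm.col_range


def assign_signatures(region_vectors: pd.DataFrame, H: np.ndarray) -> pd.DataFrame:
    """Assign each region to its dominant signature via NNLS.

    Each (encoded, scaled) region vector is regressed on the signature rows
    with nonnegative coefficients; the signature with the highest weight is
    responsible.  All-zero vectors and exact ties are left unassigned.
    """
    Ht = np.asarray(H, dtype=float).T  # features x k
    rows = []
    for rid, vec in region_vectors.iterrows():
        v = np.clip(vec.to_numpy(dtype=float), 0, None)
        if not v.any():
            rows.append({"region": rid, "signature": None, "weights": np.zeros(Ht.shape[1])})
            continue
        w, _ = nnls(Ht, v)
        top = w.max()
        winners = np.flatnonzero(w == top)
        sig = int(winners[0]) if len(winners) == 1 and top > 0 else None
        rows.append({"region": rid, "signature": sig, "weights": w})
    out = pd.DataFrame(rows).set_index("region")
    for j in range(Ht.shape[1]):
        out[f"w{j}"] = out["weights"].map(lambda w: float(w[j]))
    return out.drop(columns=["weights"])


def chromosome_zone(
    region,
    centromeres: dict,
    telomeres: dict,
    chrom_sizes: dict | None = None,
    d_bp: int = 5_000_000,
) -> str:
    """Classify a region as pericentromeric, subtelomeric or interstitial.

    Distances are measured from the region's nearest edge to the nearest
    centromere/telomere boundary.  A region within ``d_bp`` of both a
    centromere and a telomere is labeled pericentromeric.
    """
    chrom = region.chrom
    if chrom not in centromeres or chrom not in telomeres:
        raise ValueError(f"no centromere/telomere coordinates for {chrom}")

    def dist_to(iv):
        s, e = iv
        if region.end > s and region.start < e:
            return 0
        return s - region.end if region.end <= s else region.start - e

    cen_d = dist_to(centromeres[chrom])
    tel_d = min(dist_to(t) for t in telomeres[chrom])
    if cen_d < d_bp:
        return "pericentromeric"
    if tel_d < d_bp:
        return "subtelomeric"
    return "interstitial"
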