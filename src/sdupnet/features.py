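"""Genomic features of duplicated regions and their association with rates.

Features are measured either inside a region (between its breakpoints) or on
the two 50-bp flanks padding it; flanks are not distinguished — counts are
summed and means averaged over the pair.  Four kinds of measurement exist:

* ``count`` — number of track intervals overlapping the query by >= 1 bp
* ``mean`` / ``fraction`` — overlap-length-weighted mean of the track value
* ``span`` — max minus min of the track value over the query, used with
  replication timing as a proxy for replication pausing (reduced polymerase
  velocity in timing-transition regions)

Association testing is two-pronged: a permutation-calibrated random-forest
feature importance (response permuted, forest refitted, empirical p per
feature) and partial Spearman correlations controlling for all remaining
features, with Fisher-transform confidence intervals.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_score

__all__ = [
    "FeatureTrack",
    "extract_features",
    "attach_network_features",
    "background_comparison",
    "breakpoint_window_profile",
    "rf_importance",
    "partial_spearman",
]


@dataclass
class FeatureTrack:
    """One genomic track: intervals (count kinds) or interval+value series."""

    name: str
    kind: str  # count | mean | fraction | span
    position: str = "inside"  # inside | flank
    intervals: Sequence = ()  # (chrom, start, end) or (chrom, start, end, value)

    def __post_init__(self) -> None:
        if self.kind not in ("count", "mean", "fraction", "span"):
            raise ValueError(f"unknown track kind {self.kind!r}")
        if self.position not in ("inside", "flank"):
            raise ValueError(f"unknown track position {self.position!r}")
        by_chrom: dict[str, list] = {}
        for row in self.intervals:
            by_chrom.setdefault(row[0], []).append(row[1:])
        self._index = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            vals = (
                np.array([r[2] for r in rows], dtype=float)
                if self.kind != "count"
                else None
            )
            self._index[chrom] = (starts, ends, np.sort(ends), vals)

    def _overlapping(self, chrom: str, start: int, end: int):
        entry = self._index.get(chrom)
        if entry is None:
            return None
        starts, ends, _sorted_ends, vals = entry
        lo = bisect_left(starts, start)
        while lo > 0 and ends[lo - 1] > start:
            lo -= 1
        hi = bisect_right(starts, end - 1)
        idx = [i for i in range(lo, hi) if ends[i] > start and starts[i] < end]
        return starts, ends, vals, idx

    def count(self, chrom: str, start: int, end: int) -> int:
        entry = self._index.get(chrom)
        if entry is None:
            return 0
        starts, _ends, sorted_ends, _ = entry
        # overlapping = total - (end <= start) - (start >= end)
        return len(starts) - bisect_right(sorted_ends, start) - (len(starts) - bisect_left(starts, end))

    def measure(self, chrom: str, start: int, end: int):
        """Value of this track over one interval; None when no data."""
        if end <= start:
            return None
        if self.kind == "count":
            return self.count(chrom, start, end)
        got = self._overlapping(chrom, start, end)
        if got is None:
            return None
        starts, ends, vals, idx = got
        if not idx:
            return None
        if self.kind == "span":
            vv = vals[idx]
            return float(vv.max() - vv.min())
        weights = np.array(
            [min(ends[i], end) - max(starts[i], start) for i in idx], dtype=float
        )
        return float(np.average(vals[idx], weights=weights))

    def chrom_mean(self, chrom: str):
        entry = self._index.get(chrom)
        if entry is None or entry[3] is None or len(entry[3]) == 0:
            return 0.0
        return float(entry[3].mean())


def _flanks(start: int, end: int, flank_bp: int, chrom_size: int | None):
    left = (max(0, start - flank_bp), start)
    right = (end, end + flank_bp if chrom_size is None else min(end + flank_bp, chrom_size))
    truncated = left[1] - left[0] < flank_bp or right[1] - right[0] < flank_bp
    return left, right, truncated


def extract_features(
    regions,
    tracks: Sequence[FeatureTrack],
    flank_bp: int = 50,
    chrom_sizes: dict | None = None,
) -> pd.DataFrame:
    """Per-region feature matrix, one column per track.

    Count-kind flank features sum the two flanks; mean/fraction kinds
    average them.  Mean/fraction values missing inside a region fall back
    to the chromosome-wide track mean and span kinds to 0; a
    ``<name>_missing`` indicator column is added for any track with
    fallbacks.  Flanks truncated at a chromosome boundary set the
    ``flank_truncated`` flag.
    """
    rows = []
    missing_cols: dict[str, list] = {}
    for reg in regions:
        row: dict = {"region": reg.id}
        size = chrom_sizes.get(reg.chrom) if chrom_sizes else None
        left, right, truncated = _flanks(reg.start, reg.end, flank_bp, size)
        row["flank_truncated"] = truncated
        for tr in tracks:
            if tr.position == "inside":
                val = tr.measure(reg.chrom, reg.start, reg.end)
            else:
                v1 = tr.measure(reg.chrom, *left)
                v2 = tr.measure(reg.chrom, *right)
                if tr.kind == "count":
                    val = (v1 or 0) + (v2 or 0)
                else:
                    present = [v for v in (v1, v2) if v is not None]
                    val = float(np.mean(present)) if present else None
            if val is None:
                missing_cols.setdefault(tr.name, []).append(reg.id)
                val = 0.0 if tr.kind in ("span", "count") else tr.chrom_mean(reg.chrom)
            row[tr.name] = val
        rows.append(row)
    df = pd.DataFrame(rows).set_index("region")
    for name, ids in missing_cols.items():
        df[f"{name}_missing"] = df.index.isin(ids).astype(int)
    return df


def attach_network_features(df: pd.DataFrame, net) -> pd.DataFrame:
    """Add network-derived columns: length, intrachromosomal edge fraction,
    self-loops, double edges and degree."""
    df = df.copy()
    lengths, frac_intra, self_loops, doubles, degrees = {}, {}, {}, {}, {}
    for n in net.nodes:
        d = net.nodes[n]
        lengths[n] = d["end"] - d["start"]
        self_loops[n] = d["self_loop_count"]
        doubles[n] = d["n_double_edges"]
        deg = net.degree(n)
        degrees[n] = deg
        intra = sum(1 for nbr in net.neighbors(n) if net.edges[n, nbr]["intrachromosomal"])
        frac_intra[n] = intra / deg if deg else 0.0
    for col, mapping in (
        ("length", lengths),
        ("frac_intrachromosomal", frac_intra),
        ("self_loops", self_loops),
        ("n_double_edges", doubles),
        ("degree", degrees),
    ):
        df[col] = df.index.map(mapping)
    return df


def _allowed_segments(chrom_sizes: dict, gaps) -> dict:
    """Gap-free segments per chromosome."""
    gaps_by_chrom: dict[str, list] = {}
    for c, s, e in gaps:
        gaps_by_chrom.setdefault(c, []).append((s, e))
    segs: dict[str, list] = {}
    for chrom, size in chrom_sizes.items():
        pos, out = 0, []
        for s, e in sorted(gaps_by_chrom.get(chrom, [])):
            if s > pos:
                out.append((pos, s))
            pos = max(pos, e)
        if pos < size:
            out.append((pos, size))
        segs[chrom] = out
    return segs


def _place_random(lengths, segs: dict, rng) -> list:
    flat = [(chrom, s, e) for chrom, ss in segs.items() for s, e in ss]
    seg_lens = np.array([e - s for _, s, e in flat], dtype=float)
    placed = []
    for L in lengths:
        weights = np.clip(seg_lens - L + 1, 0, None)
        total = weights.sum()
        if total <= 0:
            raise ValueError(f"no gap-free stretch can host a region of length {L}")
        i = int(np.searchsorted(np.cumsum(weights), rng.random() * total))
        chrom, s, e = flat[min(i, len(flat) - 1)]
        start = int(rng.integers(s, e - L + 1))
        placed.append((chrom, start, start + L))
    return placed


@dataclass
class _Placed:
    id: int
    chrom: str
    start: int
    end: int


def background_comparison(
    regions,
    tracks: Sequence[FeatureTrack],
    chrom_sizes: dict,
    gaps=(),
    n_shuffles: int = 100,
    seed: int = 0,
    flank_bp: int = 50,
) -> pd.DataFrame:
    """Observed feature means vs. a shuffled-placement background.

    Each shuffle re-places every region (length preserved) uniformly in the
    gap-free genome and records per-feature means; the observed mean is
    tested two-sided against a normal with the shuffles' mean and sample
    variance, Bonferroni-corrected over features.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2 (background variance undefined)")
    rng = np.random.default_rng(seed)
    segs = _allowed_segments(chrom_sizes, gaps)
    obs = extract_features(regions, tracks, flank_bp=flank_bp, chrom_sizes=chrom_sizes)
    feat_names = [t.name for t in tracks]
    obs_means = obs[feat_names].mean()

    lengths = [r.end - r.start for r in regions]
    bg = np.empty((n_shuffles, len(feat_names)))
    for i in range(n_shuffles):
        placed = [
            _Placed(j, c, s, e) for j, (c, s, e) in enumerate(_place_random(lengths, segs, rng))
        ]
        shuf = extract_features(placed, tracks, flank_bp=flank_bp, chrom_sizes=chrom_sizes)
        bg[i] = shuf[feat_names].mean().to_numpy()

    mu = bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=1)
    rows = []
    for j, name in enumerate(feat_names):
        if sd[j] == 0:
            z = 0.0 if obs_means[name] == mu[j] else np.inf * np.sign(obs_means[name] - mu[j])
        else:
            z = (obs_means[name] - mu[j]) / sd[j]
        p = float(2 * stats.norm.sf(abs(z)))
        rows.append(
            {
                "feature": name,
                "observed_mean": obs_means[name],
                "background_mean": mu[j],
                "background_sd": sd[j],
                "z": z,
                "p": p,
                "p_bonferroni": min(1.0, p * len(feat_names)),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def breakpoint_window_profile(
    regions,
    repeat_track: FeatureTrack,
    chrom_sizes: dict,
    win_bp: int = 50,
    n_inside: int = 5,
    n_outside: int = 30,
    n_random: int = 10,
    seed: int = 0,
) -> dict:
    """Repeat frequency in paired windows sliding across region breakpoints.

    Windows of ``win_bp`` move as symmetric pairs from both breakpoints:
    ``n_outside`` steps away from the region (offset 0 is the window
    touching the breakpoint) and ``n_inside`` steps into it (negative
    offsets; -1 touches the breakpoint from inside).  A repeat counts when
    it overlaps a window by >= 1 bp; the frequency at an offset is the
    total count divided by the number of windows evaluated there.  The same
    scheme at ``n_random`` random genomic placements of all regions gives
    the background band.
    """
    offsets = list(range(-n_inside, 0)) + list(range(n_outside))

    def windows_for(chrom, start, end, offset):
        out = []
        if offset >= 0:  # outside
            out.append((chrom, start - win_bp * (offset + 1), start - win_bp * offset))
            out.append((chrom, end + win_bp * offset, end + win_bp * (offset + 1)))
        else:  # inside; offset -1 abuts the breakpoint
            k = -offset
            left = (chrom, start + win_bp * (k - 1), start + win_bp * k)
            right = (chrom, end - win_bp * k, end - win_bp * (k - 1))
            # short regions contribute only windows that fit inside
            if left[2] <= end:
                out.append(left)
            if right[1] >= start:
                out.append(right)
        size = chrom_sizes.get(chrom)
        return [
            (c, s, e)
            for c, s, e in out
            if s >= 0 and (size is None or e <= size)
        ]

    def profile(regs):
        freq = np.zeros(len(offsets))
        nwin = np.zeros(len(offsets))
        for chrom, start, end in regs:
            for oi, off in enumerate(offsets):
                for c, s, e in windows_for(chrom, start, end, off):
                    nwin[oi] += 1
                    freq[oi] += repeat_track.count(c, s, e)
        with np.errstate(invalid="ignore"):
            return np.where(nwin > 0, freq / np.maximum(nwin, 1), 0.0), nwin

    observed_regs = [(r.chrom, r.start, r.end) for r in regions]
    observed, n_windows = profile(observed_regs)

    rng = np.random.default_rng(seed)
    segs = _allowed_segments(chrom_sizes, [])
    lengths = [e - s for _, s, e in observed_regs]
    random_profiles = np.empty((n_random, len(offsets)))
    for i in range(n_random):
        placed = _place_random(lengths, segs, rng)
        random_profiles[i], _ = profile(placed)
    return {
        "offsets": offsets,
        "frequency": observed,
        "n_windows": n_windows,
        "random": random_profiles,
    }


def rf_importance(
    X: pd.DataFrame,
    y,
    n_trees: int = 500,
    n_perm: int = 1000,
    cv_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Random-forest importances with response-permutation p-values.

    Impurity importances are biased toward high-cardinality features; the
    permutation scheme (refit on shuffled responses, empirical p = fraction
    of permutations with importance >= observed) calibrates them.  Also
    reports the k-fold cross-validated R² of the forest.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    rng = np.random.default_rng(seed)

    def fit_importances(target):
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(X.to_numpy(), target)
        return rf.feature_importances_

    observed = fit_importances(y)
    exceed = np.zeros(X.shape[1])
    for _ in range(n_perm):
        perm = fit_importances(rng.permutation(y))
        exceed += perm >= observed
    pvals = exceed / n_perm

    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    rf = RandomForestRegressor(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    r2 = cross_val_score(rf, X.to_numpy(), y, cv=cv, scoring="r2")
    table = pd.DataFrame(
        {"importance": observed, "p_empirical": pvals}, index=X.columns
    )
    return {"table": table, "cv_r2": float(np.mean(r2)), "cv_r2_folds": r2.tolist()}


def _rank(a: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, a)


def partial_spearman(X: pd.DataFrame, y, method: str = "residual") -> pd.DataFrame:
    """Partial Spearman correlation of each feature with y given the rest.

    All columns are rank-transformed; the partial correlation comes either
    from the precision matrix of the joint correlation matrix (default) or
    from residualizing feature and response on the remaining features —
    the two are algebraically identical.  Confidence intervals use the
    Fisher transformation with variance 1/(n - g - 3), g = number of
    controlled variables; p-values use the t distribution with n - 2 - g
    degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    n, f = X.shape
    if n <= f + 2:
        raise ValueError("need more rows than features + 2")
    ranked = _rank(np.column_stack([X.to_numpy(dtype=float), y]))
    corr = np.corrcoef(ranked, rowvar=False)
    # a feature perfectly correlated with the response is a legitimate answer;
    # collinearity *among features* makes the controls ill-posed
    feat_corr = corr[:f, :f]
    if np.linalg.matrix_rank(feat_corr) < f:
        cols = list(X.columns)
        bad = [
            f"{cols[i]}~{cols[j]}"
            for i in range(f)
            for j in range(i + 1, f)
            if abs(feat_corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"collinear feature block: {', '.join(bad) or 'rank-deficient'}")

    g = f - 1  # controls per tested feature
    prec = np.linalg.inv(corr) if method == "precision" else None
    rows = []
    for j, name in enumerate(X.columns):
        rho_simple = corr[j, -1]
        if method == "precision":
            rho_p = -prec[j, -1] / np.sqrt(prec[j, j] * prec[-1, -1])
        elif method == "residual":
            others = [k for k in range(f) if k != j]
            Z = np.column_stack([np.ones(n), ranked[:, others]]) if others else np.ones((n, 1))
            beta_x, *_ = np.linalg.lstsq(Z, ranked[:, j], rcond=None)
            beta_y, *_ = np.linalg.lstsq(Z, ranked[:, -1], rcond=None)
            rx = ranked[:, j] - Z @ beta_x
            ry = ranked[:, -1] - Z @ beta_y
            rho_p = float(np.corrcoef(rx, ry)[0, 1])
        else:
            raise ValueError("method must be 'precision' or 'residual'")
        rho_p = float(np.clip(rho_p, -1.0, 1.0))
        se = 1.0 / np.sqrt(max(n - g - 3, 1))
        zr = np.arctanh(np.clip(rho_p, -0.999999, 0.999999))
        ci = (float(np.tanh(zr - 1.959964 * se)), float(np.tanh(zr + 1.959964 * se)))
        df_t = n - 2 - g
        if abs(rho_p) >= 1.0:
            p = 0.0
        else:
            t = rho_p * np.sqrt(df_t / (1 - rho_p**2))
            p = float(2 * stats.t.sf(abs(t), df_t))
        rows.append(
            {
                "feature": name,
                "rho_partial": rho_p,
                "rho_simple": float(rho_simple),
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
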