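"""Extremely randomized trees regression for sparse count features.

The estimator follows the extra-trees recipe: an ensemble of unpruned
regression trees in which every node draws a random subset of candidate
features (each feature is considered with probability ``max_features``)
and a single uniform-random threshold per candidate, keeping the candidate
with the best variance reduction; predictions are averaged across trees
and feature importances are impurity (variance) decreases weighted by the
fraction of samples reaching each node.

The implementation is specialized for wide, very sparse matrices of small
non-negative counts (such as UTR k-mer features: ~10^5 columns, most with
a single distinct nonzero value).  Node statistics are kept as dense
per-feature (count, sum y, sum y^2) accumulators — plus suffix histograms
over the distinct values of the few multi-valued features — and updated
decrementally while descending the tree, so each node's candidate scan is
a branch-free streaming pass costing O(features) independent of node
size.  A generic splitter on the same data is orders of magnitude slower
at this scale because deep "peeling" chains (the typical extra-trees
shape on sparse counts) force it to re-extract feature values at every
level.

Determinism: a self-contained xorshift64* generator seeded from
``random_state`` makes fits bit-reproducible across runs and platforms.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numba import njit

_UMASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53
_BIG = 1e300


@njit(cache=True, inline="always")
def _rand_raw(state):
    s = state[0]
    s ^= (s << np.uint64(13)) & _UMASK
    s ^= s >> np.uint64(7)
    s ^= (s << np.uint64(17)) & _UMASK
    state[0] = s
    return s


@njit(cache=True, inline="always")
def _rand(state):
    return ((_rand_raw(state) >> np.uint64(11))
            & np.uint64(0x1FFFFFFFFFFFFF)) * _INV53


@njit(cache=True)
def _token_classes(r_indices, r_data, gslot, gvoff, gvals):
    """Rank of each CSR token's value among its feature's distinct values.

    Single-valued features always get class 0; multi-valued ("general")
    features get the index of the value in their ascending vocabulary.
    """
    cls = np.zeros(len(r_indices), dtype=np.int32)
    for i in range(len(r_indices)):
        g = gslot[r_indices[i]]
        if g < 0:
            continue
        lo, hi = gvoff[g], gvoff[g + 1]
        v = r_data[i]
        while lo < hi:
            mid = (lo + hi) // 2
            if gvals[mid] < v:
                lo = mid + 1
            else:
                hi = mid
        cls[i] = lo - gvoff[g]
    return cls


@njit(cache=True)
def _add_row(r, sign, yv, r_indptr, r_indices, cls_csr, gslot, gvoff,
             cnt0, sy0, sy20, gcnt, gsy, gsy2):
    s32 = np.float32(sign)
    y2 = s32 * np.float32(yv * yv)
    yv32 = s32 * np.float32(yv)
    si = np.int32(sign)
    for idx in range(r_indptr[r], r_indptr[r + 1]):
        f = r_indices[idx]
        g = gslot[f]
        if g < 0:
            cnt0[f] += si
            sy0[f] += yv32
            sy20[f] += y2
        else:
            off = gvoff[g]
            for j in range(cls_csr[idx] + 1):
                gcnt[off + j] += si
                gsy[off + j] += yv32
                gsy2[off + j] += y2


@njit(cache=True)
def _build_tree(seed, y, r_indptr, r_indices, r_data, cls_csr,
                c_indptr, c_rows, c_data, gslot, gfeat, gvoff, gvals, val0,
                max_features, min_samples_split, min_samples_leaf,
                feature, threshold, left, right, value, importance):
    n = len(y)
    p = len(gslot)
    n_general = len(gfeat)
    state = np.empty(1, dtype=np.uint64)
    state[0] = seed
    use_bits = max_features == 0.5  # hot case: one random bit per feature

    cnt0 = np.zeros(p, dtype=np.int32)
    sy0 = np.zeros(p, dtype=np.float32)
    sy20 = np.zeros(p, dtype=np.float32)
    scores = np.empty(p, dtype=np.float32)
    words = np.empty((p >> 6) + 1, dtype=np.uint64)
    gcnt = np.zeros(len(gvals), dtype=np.int32)
    gsy = np.zeros(len(gvals), dtype=np.float32)
    gsy2 = np.zeros(len(gvals), dtype=np.float32)
    in_node = np.zeros(n, dtype=np.uint8)
    inv32 = np.zeros(n + 1, dtype=np.float32)
    for i in range(1, n + 1):
        inv32[i] = np.float32(1.0 / i)

    # pending internal right-children: rows stored in a shared buffer
    pend_rows = np.empty(n, dtype=np.int64)
    pend_start = np.empty(64, dtype=np.int64)
    pend_len = np.empty(64, dtype=np.int64)
    pend_node = np.empty(64, dtype=np.int64)
    n_pend = 0
    pend_used = 0

    for r in range(n):
        in_node[r] = 1
        _add_row(r, 1, y[r], r_indptr, r_indices, cls_csr, gslot, gvoff,
                 cnt0, sy0, sy20, gcnt, gsy, gsy2)
    n_node = n
    sy_node = 0.0
    sy2_node = 0.0
    for r in range(n):
        sy_node += y[r]
        sy2_node += y[r] * y[r]

    node_count = 1
    cur = 0  # node id whose statistics are currently loaded

    while True:
        make_leaf = False
        best_f = -1
        best_t = -1.0
        best_jr = 0
        best_general = False
        if n_node < min_samples_split:
            make_leaf = True
        else:
            fn = float(n_node)
            sse_node = sy2_node - sy_node * sy_node / fn
            if sse_node <= 1e-12:
                make_leaf = True
            else:
                best_score = sy_node * sy_node / fn + 1e-12

                # --- branch-free scan over single-valued features ---
                if use_bits:
                    for w in range(len(words)):
                        words[w] = _rand_raw(state)
                else:
                    for w in range(len(words)):
                        words[w] = np.uint64(0)
                    for f in range(p):
                        if _rand(state) < max_features:
                            words[f >> 6] |= np.uint64(1) << np.uint64(f & 63)
                sy32 = np.float32(sy_node)
                big32 = np.float32(1e30)
                one32 = np.float32(1.0)
                for f in range(p):
                    n_r = np.int64(cnt0[f])
                    n_l = n_node - n_r
                    sy_r = sy0[f]
                    sy_l = sy32 - sy_r
                    s = sy_r * sy_r * inv32[n_r] + sy_l * sy_l * inv32[n_l]
                    bad = np.float32((n_r < min_samples_leaf)
                                     | (n_l < min_samples_leaf))
                    inc = np.float32((words[f >> 6] >> np.uint64(f & 63))
                                     & np.uint64(1))
                    scores[f] = s - big32 * (bad + (one32 - inc))
                fbest = np.argmax(scores)
                if np.float64(scores[fbest]) > best_score:
                    n_r = np.int64(cnt0[fbest])
                    sy_r = np.float64(sy0[fbest])
                    n_l = n_node - n_r
                    sy_l = sy_node - sy_r
                    best_score = sy_r * sy_r / n_r + sy_l * sy_l / n_l
                    best_f = fbest

                # --- general (multi-valued) features ---
                for g in range(n_general):
                    if _rand(state) >= max_features:
                        continue
                    off = gvoff[g]
                    m = gvoff[g + 1] - off
                    n_nz = np.int64(gcnt[off])
                    if n_nz == 0:
                        continue
                    jtop = m - 1
                    while gcnt[off + jtop] == 0:
                        jtop -= 1
                    vmax = np.float64(gvals[off + jtop])
                    if n_nz < n_node:
                        vmin = 0.0
                    else:
                        jbot = 0
                        while True:
                            nxt = gcnt[off + jbot + 1] if jbot + 1 < m else 0
                            if gcnt[off + jbot] - nxt > 0:
                                break
                            jbot += 1
                        vmin = np.float64(gvals[off + jbot])
                    if vmax <= vmin:
                        continue  # constant in this node
                    t = vmin + _rand(state) * (vmax - vmin)
                    jr = jtop
                    while jr > 0 and gvals[off + jr - 1] > t:
                        jr -= 1
                    n_r = np.int64(gcnt[off + jr])
                    n_l = n_node - n_r
                    if n_r < min_samples_leaf or n_l < min_samples_leaf \
                            or n_r == 0 or n_l == 0:
                        continue
                    sy_r = np.float64(gsy[off + jr])
                    sy_l = sy_node - sy_r
                    score = sy_r * sy_r / n_r + sy_l * sy_l / n_l
                    if score > best_score:
                        best_score = score
                        best_f = gfeat[g]
                        best_t = t
                        best_jr = jr
                        best_general = True
                if best_f < 0:
                    make_leaf = True

        if not make_leaf:
            if best_general:
                off = gvoff[gslot[best_f]] + best_jr
                n_r = np.int64(gcnt[off])
                sy_r = np.float64(gsy[off])
                sy2_r = np.float64(gsy2[off])
            else:
                # single-valued winner: any threshold in [0, v) is the
                # same zero/nonzero partition; draw it now
                best_t = _rand(state) * np.float64(val0[best_f])
                n_r = np.int64(cnt0[best_f])
                sy_r = np.float64(sy0[best_f])
                sy2_r = np.float64(sy20[best_f])
            n_l = n_node - n_r
            sy_l = sy_node - sy_r
            sy2_l = sy2_node - sy2_r
            sse_node = sy2_node - sy_node * sy_node / n_node
            dec = sse_node - (sy2_r - sy_r * sy_r / n_r) \
                - (sy2_l - sy_l * sy_l / n_l)
            if dec > 0.0:
                importance[best_f] += dec
            lid = node_count
            rid = node_count + 1
            node_count += 2
            feature[cur] = best_f
            threshold[cur] = best_t
            left[cur] = lid
            right[cur] = rid

            right_leaf = n_r < min_samples_split
            if right_leaf:
                feature[rid] = -1
                value[rid] = sy_r / n_r
            elif n_pend >= len(pend_node) - 1:
                # pending stack full (cannot happen for sane inputs)
                feature[rid] = -1
                value[rid] = sy_r / n_r
                right_leaf = True

            # collect right rows; remove them from the current statistics
            start = pend_used
            cnt = 0
            for idx in range(c_indptr[best_f], c_indptr[best_f + 1]):
                r = c_rows[idx]
                if in_node[r] == 1 and c_data[idx] > best_t:
                    pend_rows[start + cnt] = r
                    cnt += 1
            for i2 in range(cnt):
                r = pend_rows[start + i2]
                in_node[r] = 0
                _add_row(r, -1, y[r], r_indptr, r_indices, cls_csr, gslot,
                         gvoff, cnt0, sy0, sy20, gcnt, gsy, gsy2)
            if not right_leaf:
                pend_start[n_pend] = start
                pend_len[n_pend] = cnt
                pend_node[n_pend] = rid
                n_pend += 1
                pend_used += cnt
            n_node = n_l
            sy_node = sy_l
            sy2_node = sy2_l
            cur = lid
            continue

        # current node becomes a leaf
        feature[cur] = -1
        value[cur] = sy_node / n_node if n_node > 0 else 0.0

        if n_pend == 0:
            break
        # rebuild statistics for the next pending subtree
        n_pend -= 1
        start = pend_start[n_pend]
        cnt = pend_len[n_pend]
        cur = pend_node[n_pend]
        pend_used = start
        cnt0[:] = 0
        sy0[:] = 0.0
        sy20[:] = 0.0
        gcnt[:] = 0
        gsy[:] = 0.0
        gsy2[:] = 0.0
        in_node[:] = 0
        n_node = np.int64(cnt)
        sy_node = 0.0
        sy2_node = 0.0
        for i2 in range(cnt):
            r = pend_rows[start + i2]
            in_node[r] = 1
            sy_node += y[r]
            sy2_node += y[r] * y[r]
            _add_row(r, 1, y[r], r_indptr, r_indices, cls_csr, gslot, gvoff,
                     cnt0, sy0, sy20, gcnt, gsy, gsy2)
    return node_count


@njit(cache=True)
def _predict_tree(r_indptr, r_indices, r_data, feature, threshold,
                  left, right, value, out):
    n = len(r_indptr) - 1
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            f = feature[node]
            lo, hi = r_indptr[i], r_indptr[i + 1]
            v = 0.0
            while lo < hi:
                mid = (lo + hi) // 2
                if r_indices[mid] < f:
                    lo = mid + 1
                else:
                    hi = mid
            if lo < r_indptr[i + 1] and r_indices[lo] == f:
                v = r_data[lo]
            if v <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] += value[node]


class SparseExtraTreesRegressor:
    """Extra-trees regressor specialized for sparse non-negative counts.

    Parameters mirror the usual ensemble conventions: ``n_estimators``
    trees; each node considers every feature independently with probability
    ``max_features`` and one random threshold; nodes split only with at
    least ``min_samples_split`` samples.  ``feature_importances_`` are
    impurity decreases summed over nodes and trees, normalized to 1.
    """

    def __init__(self, n_estimators: int = 100, max_features: float = 0.5,
                 min_samples_split: int = 100, min_samples_leaf: int = 1,
                 random_state: int = 0):
        if not 0 < max_features <= 1:
            raise ValueError("max_features must be in (0, 1]")
        if min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    @staticmethod
    def _prepare(X):
        # float32 keeps the value vocabulary and raw values bit-consistent
        Xr = sp.csr_matrix(X, dtype=np.float32)
        Xr.sort_indices()
        return Xr

    def fit(self, X, y):
        Xr = self._prepare(X)
        y = np.ascontiguousarray(np.asarray(y, dtype=np.float64))
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite regression targets")
        if Xr.shape[0] != len(y):
            raise ValueError("X and y disagree on sample count")
        if Xr.data.size and Xr.data.min() < 0:
            raise ValueError("negative feature values are not supported")
        n, p = Xr.shape
        Xc = Xr.tocsc()
        Xc.sort_indices()

        # distinct nonzero values per feature, ascending (flat layout)
        col_of = np.repeat(np.arange(p, dtype=np.int64), np.diff(Xc.indptr))
        order = np.lexsort((Xc.data, col_of))
        cc, vv = col_of[order], Xc.data[order]
        if len(cc):
            first = np.empty(len(cc), dtype=bool)
            first[0] = True
            first[1:] = (cc[1:] != cc[:-1]) | (vv[1:] != vv[:-1])
            uvals, ucols = vv[first], cc[first]
        else:
            uvals = np.empty(0, dtype=np.float32)
            ucols = np.empty(0, dtype=np.int64)
        m_per_f = np.bincount(ucols, minlength=p)
        val0 = np.zeros(p, dtype=np.float32)
        mask_single = m_per_f[ucols] == 1
        val0[ucols[mask_single]] = uvals[mask_single]
        gfeat = np.flatnonzero(m_per_f >= 2).astype(np.int64)
        gslot = np.full(p, -1, dtype=np.int64)
        gslot[gfeat] = np.arange(len(gfeat))
        keep = m_per_f[ucols] >= 2
        gvals = uvals[keep].astype(np.float32)
        gvoff = np.zeros(len(gfeat) + 1, dtype=np.int64)
        np.add.at(gvoff, gslot[ucols[keep]] + 1, 1)
        gvoff = np.cumsum(gvoff)

        r_indptr = Xr.indptr.astype(np.int64)
        r_indices = Xr.indices.astype(np.int64)
        r_data = Xr.data
        cls_csr = _token_classes(r_indices, r_data, gslot, gvoff, gvals)
        c_indptr = Xc.indptr.astype(np.int64)
        c_rows = Xc.indices.astype(np.int64)
        c_data = Xc.data

        seeds = np.random.SeedSequence(self.random_state).generate_state(
            self.n_estimators, dtype=np.uint64) | np.uint64(1)
        max_nodes = 2 * n + 1
        self.trees_ = []
        importance = np.zeros(p, dtype=np.float64)
        for s in seeds:
            feature = np.full(max_nodes, -1, dtype=np.int64)
            threshold = np.zeros(max_nodes, dtype=np.float64)
            left = np.zeros(max_nodes, dtype=np.int64)
            right = np.zeros(max_nodes, dtype=np.int64)
            value = np.zeros(max_nodes, dtype=np.float64)
            nc = _build_tree(s, y, r_indptr, r_indices, r_data, cls_csr,
                             c_indptr, c_rows, c_data, gslot, gfeat, gvoff,
                             gvals, val0, float(self.max_features),
                             int(self.min_samples_split),
                             int(self.min_samples_leaf),
                             feature, threshold, left, right, value,
                             importance)
            self.trees_.append((feature[:nc].copy(), threshold[:nc].copy(),
                                left[:nc].copy(), right[:nc].copy(),
                                value[:nc].copy()))
        total = importance.sum()
        self.feature_importances_ = (importance / total if total > 0
                                     else importance)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        Xr = self._prepare(X)
        if Xr.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        out = np.zeros(Xr.shape[0], dtype=np.float64)
        r_indptr = Xr.indptr.astype(np.int64)
        r_indices = Xr.indices.astype(np.int64)
        for feature, threshold, left, right, value in self.trees_:
            _predict_tree(r_indptr, r_indices, Xr.data, feature, threshold,
                          left, right, value, out)
        return out / len(self.trees_)
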