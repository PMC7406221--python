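"""UTR k-mer feature matrices.

Features are overlapping occurrence counts of every 3- to 8-mer in the
5' UTR proxy (150 nt upstream) and the 3' UTR proxy (100 nt downstream),
on the coding strand only.  The feature universe is fixed:
2 regions x sum_{k=3..8} 4^k = 174,720 columns, stored sparse.  Windows
containing N contribute no counts for k-mers spanning the N.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ParameterError

BASES = "ACGT"
KMIN, KMAX = 3, 8
REGIONS = ("5utr", "3utr")


def universe_size(kmin: int = KMIN, kmax: int = KMAX,
                  n_regions: int = 2) -> int:
    return n_regions * sum(4 ** k for k in range(kmin, kmax + 1))


def _k_offsets(kmin: int, kmax: int):
    offs = {}
    off = 0
    for k in range(kmin, kmax + 1):
        offs[k] = off
        off += 4 ** k
    return offs, off


def feature_index(region: str, kmer: str, kmin: int = KMIN,
                  kmax: int = KMAX) -> int:
    """Column index of a (region, k-mer) feature in the fixed universe."""
    if region not in REGIONS:
        raise ParameterError(f"unknown region {region!r}")
    k = len(kmer)
    if not (kmin <= k <= kmax):
        raise ParameterError(f"k={k} outside [{kmin}, {kmax}]")
    offs, per_region = _k_offsets(kmin, kmax)
    code = 0
    for c in kmer.upper():
        code = code * 4 + BASES.index(c)
    return REGIONS.index(region) * per_region + offs[k] + code


def feature_name(index: int, kmin: int = KMIN, kmax: int = KMAX) -> str:
    offs, per_region = _k_offsets(kmin, kmax)
    region = REGIONS[index // per_region]
    rem = index % per_region
    for k in sorted(offs, reverse=True):
        if rem >= offs[k]:
            code = rem - offs[k]
            kmer = "".join(BASES[(code >> (2 * (k - 1 - j))) & 3]
                           for j in range(k))
            return f"{region}:{kmer}"
    raise ParameterError("bad feature index")  # pragma: no cover


_ENC = np.full(256, -1, dtype=np.int64)
for i, b in enumerate(BASES):
    _ENC[ord(b)] = i
    _ENC[ord(b.lower())] = i


def _seq_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all valid (N-free) k-mers of ``seq``, overlapping."""
    codes = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return (win[valid] * powers).sum(axis=1)


def count_kmers(utrs: pd.DataFrame, kmin: int = KMIN,
                kmax: int = KMAX) -> "KmerFeatureMatrix":
    """Sparse gene x feature matrix of overlapping k-mer counts."""
    if kmin > kmax:
        raise ParameterError("kmin > kmax")
    offs, per_region = _k_offsets(kmin, kmax)
    n_feat = 2 * per_region
    indptr = [0]
    indices = []
    data = []
    for _, row in utrs.iterrows():
        cols_g = []
        cnts_g = []
        for r_ix, col in enumerate(("utr5", "utr3")):
            seq = row[col]
            base = r_ix * per_region
            for k in range(kmin, kmax + 1):
                codes = _seq_kmer_codes(seq, k)
                if len(codes) == 0:
                    continue
                uniq, cnt = np.unique(codes, return_counts=True)
                cols_g.append(base + offs[k] + uniq)
                cnts_g.append(cnt)
        if cols_g:
            cols_cat = np.concatenate(cols_g)
            order = np.argsort(cols_cat)
            indices.append(cols_cat[order])
            data.append(np.concatenate(cnts_g)[order])
            indptr.append(indptr[-1] + len(cols_cat))
        else:
            indptr.append(indptr[-1])
    X = sp.csr_matrix(
        (np.concatenate(data) if data else np.empty(0),
         np.concatenate(indices) if indices else np.empty(0, dtype=np.int64),
         np.array(indptr)),
        shape=(len(utrs), n_feat), dtype=np.float32)
    return KmerFeatureMatrix(X=X, gene_ids=utrs.index.to_list(),
                             kmin=kmin, kmax=kmax)


class KmerFeatureMatrix:
    """Sparse k-mer counts with the fixed two-region feature universe."""

    def __init__(self, X: sp.csr_matrix, gene_ids, kmin: int = KMIN,
                 kmax: int = KMAX):
        self.X = X
        self.gene_ids = list(gene_ids)
        self.kmin = kmin
        self.kmax = kmax

    @property
    def shape(self):
        return self.X.shape

    def index_of(self, region: str, kmer: str) -> int:
        return feature_index(region, kmer, self.kmin, self.kmax)

    def name_of(self, index: int) -> str:
        return feature_name(index, self.kmin, self.kmax)

    def subset(self, gene_ids) -> "KmerFeatureMatrix":
        pos = pd.Index(self.gene_ids).get_indexer(gene_ids)
        if (pos < 0).any():
            raise ParameterError("unknown gene id in subset")
        return KmerFeatureMatrix(self.X[pos], list(gene_ids),
                                 self.kmin, self.kmax)
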