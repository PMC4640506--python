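"""Independent oracles used by the test suite.

Each function here re-derives a pipeline quantity by a route deliberately
different from the package implementation (exhaustive scans, direct formula
transcriptions, scipy distribution enumerations), so that agreement is a
genuine cross-check rather than the same code run twice.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import nbinom, poisson

from mirstarve.align import revcomp


def brute_force_hits(read_seq, index, max_mm=2, both_strands=False):
    """Exhaustive alignment scan: slide the read over every feature offset,
    counting substitutions; the reverse complement is searched on
    genome-class features (all classes with both_strands).  Returns
    {(feature_id, offset, strand, mismatches)}."""
    out = set()
    rc = revcomp(read_seq)
    for feat in index:
        queries = [(read_seq, "+")]
        if both_strands or feat.seq_class == "genome":
            queries.append((rc, "-"))
        for query, strand in queries:
            for off in range(len(feat.sequence) - len(query) + 1):
                mm = sum(
                    a != b for a, b in zip(feat.sequence[off:off + len(query)], query)
                )
                if mm <= max_mm:
                    out.add((feat.feature_id, off, strand, mm))
    return out


def hitset_tuples(hitset):
    return {(h.feature_id, h.offset, h.strand, h.mismatches) for h in hitset.hits}


def naive_count_oracle(hitsets, reads, index):
    """Plain-dictionary re-derivation of class assignment and fractional
    division (floats, no shared code path).  Returns (per-feature totals,
    reads dropped by the sub-unit rule, unmapped reads)."""
    totals: dict[str, float] = {}
    dropped = unmapped = 0
    order = {"mature": 0, "hairpin": 1, "ncRNA": 2, "coding": 3, "genome": 4}
    for hs in hitsets:
        read = reads[hs.uid]
        if not hs.hits:
            unmapped += read.count
            continue
        locations = set()
        for h in hs.hits:
            cls, fid, off = h.seq_class, h.feature_id, h.offset
            if cls == "hairpin":
                feat = index[fid]
                for region in feat.mature_regions:
                    if region.start <= off and off + len(read.sequence) <= region.end:
                        cls, fid, off = "mature", region.mature_id, off - region.start
                        break
            locations.add((order[cls], fid, off, h.strand))
        top = min(loc[0] for loc in locations)
        kept = [loc for loc in locations if loc[0] == top]
        share = read.count / len(kept)
        if share < 1:
            dropped += read.count
            continue
        for _, fid, _, _ in kept:
            totals[fid] = totals.get(fid, 0.0) + share
    return totals, dropped, unmapped


def textbook_tmm(obs, ref):
    """Direct-formula TMM factor of `obs` against `ref`: doubly trimmed
    (30% of M per tail, 5% of A per tail), inverse-variance-weighted mean of
    log2 relative-proportion ratios, transcribed from the published method
    description."""
    obs, ref = np.asarray(obs, float), np.asarray(ref, float)
    n_o, n_r = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    M = np.log2((obs / n_o) / (ref / n_r))
    A = 0.5 * np.log2((obs / n_o) * (ref / n_r))
    w = 1.0 / ((n_o - obs) / (n_o * obs) + (n_r - ref) / (n_r * ref))
    n = len(M)
    lo_l, lo_s = math.floor(n * 0.3) + 1, math.floor(n * 0.05) + 1

    def ranks(x):
        order = np.argsort(x, kind="mergesort")
        r = np.empty(n)
        r[order] = np.arange(1, n + 1)
        for val in np.unique(x):
            mask = x == val
            r[mask] = r[mask].mean()
        return r

    rm, ra = ranks(M), ranks(A)
    keep2 = (rm >= lo_l) & (rm <= n + 1 - lo_l) & (ra >= lo_s) & (ra <= n + 1 - lo_s)
    return 2 ** (np.sum(M[keep2] * w[keep2]) / np.sum(w[keep2]))


def oracle_conditional_p(ka, kb, phi):
    """Enumeration oracle for the conditional NB exact test: joint
    probabilities of two iid NB (or Poisson at phi=0) counts via scipy pmfs,
    conditioned on the sum; two-sided probability-mass method."""
    s = ka + kb
    mu = 3.0  # the conditional law is free of the mean
    if phi == 0:
        joint = np.array(
            [poisson.pmf(k, mu) * poisson.pmf(s - k, mu) for k in range(s + 1)]
        )
    else:
        r = 1.0 / phi
        p = r / (r + mu)
        joint = np.array(
            [nbinom.pmf(k, r, p) * nbinom.pmf(s - k, r, p) for k in range(s + 1)]
        )
    cond = joint / joint.sum()
    return float(cond[cond <= cond[ka] * (1 + 1e-9)].sum())
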