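"""Experimental-style contact matrices: loading, comparison, fixtures.

Dense whitespace/tab-delimited square matrices with a BED-like bin table
(chrom, start_bp, end_bp) are the interchange format; desk-scale maps are
small enough that sparse storage buys nothing.  Comparison against
simulated maps uses the Pearson correlation of log2-transformed counts on
the upper triangle, after rebinning the finer map to a common resolution.

The fixture generators build contact patterns with known closed-form
mixing indices: the ideal uniform-mixing pattern distributes inter-chain
contacts in proportion to the product of chain sizes (its mixing index is
(N^2 - sum L_i^2)/sum L_i^2, i.e. n - 1 for n equal chains), the
block-diagonal pattern has none, and the graded pattern scales the
inter-chain blocks by a mixing parameter m in [0, 1].
"""

from __future__ import annotations

import gzip

import warnings

import numpy as np
import pandas as pd

from .analysis import CONTACT_CUTOFF, ContactMap, mixing_index

__all__ = [
    "load_contact_matrix",
    "save_contact_matrix",
    "hic_mixing_index",
    "pearson_log2",
    "rebin_map",
    "synth_contact_fixture",
    "synth_gaussian_chain_sample",
]


def _open_text(path, mode="rt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(
        path, mode.rstrip("t")
    )


def load_contact_matrix(matrix_path, bins_path) -> ContactMap:
    """Dense contact matrix + BED-like bin table -> ContactMap.

    The bin table rows (chrom, start_bp, end_bp) must match the matrix row
    order; chain offsets are recovered from the chromosome boundaries.
    Slightly asymmetric matrices are symmetrized by averaging with a
    warning; asymmetry beyond round-off is still symmetrized but flagged.
    """
    with _open_text(matrix_path) as fh:
        counts = np.loadtxt(fh, ndmin=2)
    bins = pd.read_csv(
        bins_path, sep="\t", header=None,
        names=["chrom", "start_bp", "end_bp"], comment="#",
        usecols=[0, 1, 2],
    )
    n = counts.shape[0]
    if counts.shape != (n, n):
        raise ValueError("contact matrix must be square")
    if len(bins) != n:
        raise ValueError(
            f"bin table has {len(bins)} rows but matrix is {n}x{n}"
        )
    if np.any(counts < 0):
        raise ValueError("negative contact counts")
    if not np.allclose(counts, counts.T, atol=1e-9, rtol=0):
        warnings.warn("asymmetric contact matrix; symmetrizing by averaging")
    counts = 0.5 * (counts + counts.T)
    chrom = bins["chrom"].to_numpy()
    boundaries = [0] + [
        i + 1 for i in range(n - 1) if chrom[i + 1] != chrom[i]
    ] + [n]
    return ContactMap(counts=counts, chain_offsets=np.array(boundaries))


def save_contact_matrix(cmap: ContactMap, matrix_path, bins_path,
                        chrom_names=None, bp_per_bin=5000):
    """Write the dense matrix and a matching BED-like bin table."""
    with _open_text(matrix_path, "wt") as fh:
        np.savetxt(fh, cmap.counts, fmt="%.17g", delimiter="\t")
    if chrom_names is None:
        chrom_names = [f"chr{i + 1}" for i in range(cmap.n_chains)]
    rows = []
    for c in range(cmap.n_chains):
        lo, hi = cmap.chain_offsets[c], cmap.chain_offsets[c + 1]
        for b in range(hi - lo):
            rows.append(
                (chrom_names[c], b * bp_per_bin, (b + 1) * bp_per_bin)
            )
    pd.DataFrame(rows).to_csv(bins_path, sep="\t", header=False, index=False)


def hic_mixing_index(cmap: ContactMap, exclude_band: int = 2) -> float:
    """Mixing index of an experimental map.

    Excludes the main diagonal and the first off-diagonal intra-chromosome
    band by default, mirroring the bonded-pair exclusion applied to
    simulated bead maps.
    """
    return mixing_index(cmap, exclude_band=exclude_band)


def pearson_log2(map_a: ContactMap, map_b: ContactMap,
                 pseudocount: float = 1.0) -> float:
    """Pearson correlation of log2(count + pseudocount) maps.

    Computed over the upper triangle excluding the main diagonal; the
    caller is responsible for rebinning to equal dimensions first.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if map_a.counts.shape != map_b.counts.shape:
        raise ValueError("maps must have equal dimensions (rebin first)")
    iu, ju = np.triu_indices(map_a.n_bins, k=1)
    a = np.log2(map_a.counts[iu, ju] + pseudocount)
    b = np.log2(map_b.counts[iu, ju] + pseudocount)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def rebin_map(cmap: ContactMap, factor: int, allow_remainder: bool = True
              ) -> ContactMap:
    """Block-sum aggregation by ``factor`` bins, respecting chain bounds.

    No output bin ever spans a chromosome boundary; with
    ``allow_remainder`` the last bin of a chain may be smaller, otherwise
    the factor must divide every chain span.  Total counts are conserved
    exactly, and the mixing index is invariant (within-bin contacts land on
    the diagonal, which the index counts at half weight).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    lengths = np.diff(cmap.chain_offsets)
    if factor > lengths.min():
        raise ValueError("factor exceeds the smallest chromosome span")
    assign = np.empty(cmap.n_bins, np.int64)
    new_offsets = [0]
    nb = 0
    for c in range(cmap.n_chains):
        lo, hi = cmap.chain_offsets[c], cmap.chain_offsets[c + 1]
        span = hi - lo
        if span % factor != 0 and not allow_remainder:
            raise ValueError(
                f"factor {factor} does not divide chain span {span}"
            )
        nbins_c = -(-span // factor)
        assign[lo:hi] = nb + np.arange(span) // factor
        nb += nbins_c
        new_offsets.append(nb)
    S = np.zeros((nb, cmap.n_bins))
    S[assign, np.arange(cmap.n_bins)] = 1.0
    new_counts = S @ cmap.counts @ S.T
    return ContactMap(
        counts=new_counts,
        chain_offsets=np.array(new_offsets),
        n_frames_averaged=cmap.n_frames_averaged,
        cutoff=cmap.cutoff,
    )


def synth_contact_fixture(kind, chain_lengths, total_contacts=1e6, seed=0,
                          mixing=0.5, noise=False):
    """Synthetic contact patterns with a closed-form mixing index.

    kind ``ideal_mixing``: every chain-pair block receives expected counts
    proportional to the product of chain sizes, spread uniformly over its
    allowed entries (intra entries with |i-j| >= 2); the exact mixing index
    is (N^2 - sum L^2)/sum L^2.  ``block_diagonal``: no inter-chain
    contacts, index 0.  ``graded``: inter blocks scaled by ``mixing`` m,
    index m * (N^2 - sum L^2)/sum L^2.  With ``noise`` the expected counts
    are Poisson-sampled (the closed form then holds in expectation only).

    Returns (ContactMap, closed_form_alpha).
    """
    lengths = np.asarray(chain_lengths, dtype=np.int64)
    if len(lengths) < 2:
        raise ValueError("need at least 2 chains")
    n_chains = len(lengths)
    N = int(lengths.sum())
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    sum_sq = float(np.sum(lengths.astype(float) ** 2))
    alpha_ideal = (float(N) ** 2 - sum_sq) / sum_sq
    if kind == "ideal_mixing":
        m = 1.0
    elif kind == "block_diagonal":
        m = 0.0
    elif kind == "graded":
        if not 0.0 <= mixing <= 1.0:
            raise ValueError("mixing must lie in [0, 1]")
        m = float(mixing)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    alpha = m * alpha_ideal

    counts = np.zeros((N, N))
    # weight per block: L_mu^2/2 on the diagonal blocks, m * L_mu * L_nu off
    weight = np.zeros((n_chains, n_chains))
    for a in range(n_chains):
        weight[a, a] = 0.5 * float(lengths[a]) ** 2
        for b in range(a + 1, n_chains):
            weight[a, b] = m * float(lengths[a]) * float(lengths[b])
    scale = float(total_contacts) / weight.sum()
    for a in range(n_chains):
        la = int(lengths[a])
        lo_a = offsets[a]
        # intra: uniform over pairs with contour distance >= 2
        n_entries = la * (la - 1) // 2 - (la - 1)
        if n_entries > 0:
            v = scale * weight[a, a] / n_entries
            for i in range(la):
                for j in range(i + 2, la):
                    counts[lo_a + i, lo_a + j] = v
                    counts[lo_a + j, lo_a + i] = v
        for b in range(a + 1, n_chains):
            if weight[a, b] == 0:
                continue
            lb = int(lengths[b])
            v = scale * weight[a, b] / (la * lb)
            counts[lo_a:lo_a + la, offsets[b]:offsets[b] + lb] = v
            counts[offsets[b]:offsets[b] + lb, lo_a:lo_a + la] = v
    if noise:
        rng = np.random.default_rng(seed)
        iu, ju = np.triu_indices(N, k=1)
        sampled = rng.poisson(counts[iu, ju]).astype(float)
        counts = np.zeros((N, N))
        counts[iu, ju] = sampled
        counts[ju, iu] = sampled
    cmap = ContactMap(counts=counts, chain_offsets=offsets,
                      cutoff=CONTACT_CUTOFF)
    return cmap, alpha


def synth_gaussian_chain_sample(n_beads, n_samples, seed, batch_size=None):
    """Direct-sampled freely-jointed chains with unit bond length.

    Each sample is a random walk of n_beads steps in 3D with fixed step
    length sigma (random directions uniform on the sphere) — the ideal
    (phantom) chain ensemble whose contact probability decays as s^-3/2.
    Returns an (n_samples, n_beads, 3) array, or an iterator of such
    blocks when ``batch_size`` is given (large ensembles).
    """
    if n_beads < 10:
        raise ValueError("n_beads must be >= 10")

    def make(rng, m):
        steps = rng.normal(size=(m, n_beads - 1, 3))
        steps /= np.linalg.norm(steps, axis=2, keepdims=True)
        pos = np.zeros((m, n_beads, 3))
        np.cumsum(steps, axis=1, out=pos[:, 1:, :])
        return pos

    rng = np.random.default_rng(seed)
    if batch_size is None:
        return make(rng, n_samples)

    def batches():
        done = 0
        while done < n_samples:
            m = min(batch_size, n_samples - done)
            yield make(rng, m)
            done += m

    return batches()
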