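"""Observables: contact maps, mixing index, P(s), scaling fits, MSD, R_g.

The central quantity is the chromosome mixing index

    alpha = (inter-chain contacts) / (intra-chain contacts)

computed from a contact map in which two beads are "in contact" when their
centers are closer than 1.5 sigma.  In the ideal uniform-mixing limit of n
equal chains every allowed bead pair is equally likely to touch, and alpha
attains its maximum n - 1 (3 for a four-chromosome genome).  As chains
interpenetrate, alpha grows as a power law alpha ~ t^beta; the exponent
beta and the intra-chain contact-probability exponent gamma of
P(s) ~ s^-gamma are extracted with log-log least squares.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model_core import ScalingFit

__all__ = [
    "ContactMap",
    "MixingTrace",
    "UndefinedMixingIndexError",
    "compute_contact_map",
    "ideal_mixing_alpha",
    "mixing_index",
    "mixing_trace",
    "contact_probability",
    "fit_power_law",
    "extrapolate_mixing_time",
    "classify_mixing_state",
    "msd",
    "radius_of_gyration",
    "write_mixing_grid",
    "read_mixing_grid",
    "CONTACT_CUTOFF",
    "CRITICAL_TIME_TAU",
]

CONTACT_CUTOFF = 1.5          # sigma; centers closer than this are in contact
CRITICAL_TIME_TAU = 2.68e12   # tau; ~5 years, the full-mixing critical time


class UndefinedMixingIndexError(ValueError):
    """Mixing index requested on a map with zero intra-chain contacts."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Symmetric contact-count matrix with chain boundary bookkeeping.

    ``chain_offsets`` holds the start index of each chain block plus the
    matrix size as final entry.
    """

    counts: np.ndarray
    chain_offsets: np.ndarray
    n_frames_averaged: int = 1
    cutoff: float = CONTACT_CUTOFF

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.chain_offsets = np.asarray(self.chain_offsets, dtype=np.int64)
        n = self.counts.shape[0]
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")
        offs = self.chain_offsets
        if offs[0] != 0 or offs[-1] != n or np.any(np.diff(offs) <= 0):
            raise ValueError(
                "chain_offsets must increase strictly from 0 to the matrix size"
            )
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("contact counts must be symmetric")

    @property
    def n_chains(self) -> int:
        return len(self.chain_offsets) - 1

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def chain_of_bin(self) -> np.ndarray:
        lengths = np.diff(self.chain_offsets)
        return np.repeat(np.arange(self.n_chains), lengths)

    # -- gzip TSV + JSON sidecar ------------------------------------------

    def save(self, matrix_path, sidecar_path=None):
        opener = gzip.open if str(matrix_path).endswith(".gz") else open
        with opener(matrix_path, "wt") as fh:
            np.savetxt(fh, self.counts, fmt="%.17g", delimiter="\t")
        if sidecar_path is None:
            sidecar_path = str(matrix_path) + ".json"
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "chain_offsets": self.chain_offsets.tolist(),
                    "cutoff": self.cutoff,
                    "n_frames_averaged": self.n_frames_averaged,
                },
                fh,
            )

    @classmethod
    def load(cls, matrix_path, sidecar_path=None):
        opener = gzip.open if str(matrix_path).endswith(".gz") else open
        with opener(matrix_path, "rt") as fh:
            counts = np.loadtxt(fh, delimiter="\t", ndmin=2)
        if sidecar_path is None:
            sidecar_path = str(matrix_path) + ".json"
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        return cls(
            counts=counts,
            chain_offsets=np.asarray(meta["chain_offsets"]),
            n_frames_averaged=int(meta.get("n_frames_averaged", 1)),
            cutoff=float(meta.get("cutoff", CONTACT_CUTOFF)),
        )


@dataclass
class MixingTrace:
    """Per-frame mixing index with its trailing-window time average."""

    times: np.ndarray
    alpha: np.ndarray
    alpha_max: float
    alpha_bar: float = math.nan     # trailing-window average
    window_fraction: float = 0.3

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if self.times.shape != self.alpha.shape:
            raise ValueError("times and alpha must align")
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be non-negative")


# --------------------------------------------------------------------------
# contact counting kernels
# --------------------------------------------------------------------------

@njit(cache=True)
def _accumulate_map(counts, pos, chain_id, cutoff, exclude_band):
    n = pos.shape[0]
    cut2 = cutoff * cutoff
    for i in range(n):
        for j in range(i + 1, n):
            if chain_id[i] == chain_id[j] and j - i <= exclude_band:
                continue
            d0 = pos[i, 0] - pos[j, 0]
            d1 = pos[i, 1] - pos[j, 1]
            d2 = pos[i, 2] - pos[j, 2]
            if d0 * d0 + d1 * d1 + d2 * d2 < cut2:
                counts[i, j] += 1.0
                counts[j, i] += 1.0


@njit(cache=True)
def _count_intra_inter(pos, chain_id, cutoff, exclude_band):
    n = pos.shape[0]
    cut2 = cutoff * cutoff
    intra = 0
    inter = 0
    for i in range(n):
        for j in range(i + 1, n):
            same = chain_id[i] == chain_id[j]
            if same and j - i <= exclude_band:
                continue
            d0 = pos[i, 0] - pos[j, 0]
            d1 = pos[i, 1] - pos[j, 1]
            d2 = pos[i, 2] - pos[j, 2]
            if d0 * d0 + d1 * d1 + d2 * d2 < cut2:
                if same:
                    intra += 1
                else:
                    inter += 1
    return intra, inter


@njit(cache=True)
def _ps_counts(pos, offsets, s_values, cutoff, hits, totals):
    cut2 = cutoff * cutoff
    nch = offsets.shape[0] - 1
    for c in range(nch):
        lo = offsets[c]
        hi = offsets[c + 1]
        length = hi - lo
        for k in range(s_values.shape[0]):
            s = s_values[k]
            if s >= length:
                continue
            for i in range(lo, hi - s):
                j = i + s
                d0 = pos[i, 0] - pos[j, 0]
                d1 = pos[i, 1] - pos[j, 1]
                d2 = pos[i, 2] - pos[j, 2]
                totals[k] += 1
                if d0 * d0 + d1 * d1 + d2 * d2 < cut2:
                    hits[k] += 1


def _chain_id_from_offsets(offsets):
    lengths = np.diff(np.asarray(offsets, dtype=np.int64))
    return np.repeat(np.arange(len(lengths)), lengths).astype(np.int32)


def _frames_of(traj_or_frames):
    frames = getattr(traj_or_frames, "frames", traj_or_frames)
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    return frames


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def compute_contact_map(frames, chain_offsets, cutoff=CONTACT_CUTOFF,
                        exclude_bonded=True):
    """Count frames in which each bead pair sits within the contact cutoff.

    ``frames`` is (F, N, 3) (or a single (N, 3) configuration).  Bonded
    neighbors (|i - j| <= 1 within a chain) are excluded when
    ``exclude_bonded`` — their permanent contact carries no mixing signal.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frames = _frames_of(frames)
    if frames.shape[0] == 0:
        raise ValueError("empty frame list")
    offsets = np.asarray(chain_offsets, dtype=np.int64)
    chain_id = _chain_id_from_offsets(offsets)
    n = frames.shape[1]
    if offsets[-1] != n:
        raise ValueError("chain_offsets do not match frame bead count")
    counts = np.zeros((n, n))
    band = 1 if exclude_bonded else 0
    for f in range(frames.shape[0]):
        _accumulate_map(counts, np.ascontiguousarray(frames[f]), chain_id,
                        float(cutoff), band)
    return ContactMap(
        counts=counts,
        chain_offsets=offsets,
        n_frames_averaged=frames.shape[0],
        cutoff=float(cutoff),
    )


def mixing_index(cmap: ContactMap, exclude_band: int = 0) -> float:
    """Inter-chain over intra-chain total contact count.

    For a genome of n equal chains in the ideal uniform-mixing limit this
    ratio equals n - 1.  Bead-resolution maps have a zero diagonal; on
    binned maps the diagonal holds within-bin intra contacts and enters the
    intra total at half weight so that the index is invariant under
    rebinning.  ``exclude_band`` drops the first ``exclude_band`` intra
    diagonals (band 1 = main diagonal only, 2 = main plus first
    off-diagonal; used for experimental maps whose near-diagonal is
    dominated by local structure rather than mixing).
    """
    if cmap.n_chains < 2:
        raise ValueError("mixing index needs at least 2 chains")
    chain = cmap.chain_of_bin()
    iu, ju = np.triu_indices(cmap.n_bins, k=0)
    same = chain[iu] == chain[ju]
    dist = ju - iu
    vals = cmap.counts[iu, ju] * np.where(dist == 0, 0.5, 1.0)
    if exclude_band > 0:
        keep = ~(same & (dist < exclude_band))
        same, vals = same[keep], vals[keep]
    intra = float(vals[same].sum())
    inter = float(vals[~same].sum())
    if inter == 0.0:
        return 0.0
    if intra == 0.0:
        raise UndefinedMixingIndexError("no intra-chain contacts; alpha undefined")
    return inter / intra


def ideal_mixing_alpha(chain_lengths, exclude_band=1):
    """Mixing index of the uniform-contact ideal for finite chains.

    When every allowed bead pair is equally likely to be in contact, the
    index equals (inter-chain pairs)/(intra-chain pairs counted by the
    estimator).  For n equal chains this tends to n - 1 as the chains grow
    (3.046 for 4 chains of 200 beads vs the asymptotic 3); the finite-size
    value is the right yardstick for reduced-scale simulations.
    """
    lengths = np.asarray(chain_lengths, dtype=float)
    inter = (lengths.sum() ** 2 - np.sum(lengths ** 2)) / 2.0
    intra = sum(
        l * (l - 1) / 2.0 - sum(l - d for d in range(1, exclude_band + 1))
        for l in lengths
    )
    if intra <= 0:
        raise ValueError("no intra-chain pairs at this exclusion band")
    return float(inter / intra)


def mixing_trace(trajectory, chain_offsets=None, cutoff=CONTACT_CUTOFF,
                 frame_window=0.3, exclude_band=1):
    """Per-frame mixing index alpha(t) and its trailing time average.

    The windowed average alpha_bar is taken over the trailing
    ``frame_window`` fraction of frames (default: last 30%).  Frames without
    intra-chain contacts cannot define alpha and are skipped.
    """
    frames = _frames_of(trajectory)
    if frames.shape[0] < 2:
        raise ValueError("mixing trace needs at least 2 frames")
    times = getattr(trajectory, "times", None)
    if times is None:
        times = np.arange(frames.shape[0], dtype=float)
    if chain_offsets is None:
        chain_offsets = trajectory.chain_offsets()
    offsets = np.asarray(chain_offsets, dtype=np.int64)
    if offsets[-1] != frames.shape[1]:
        # trajectory may carry trailing immobile lamin beads: analyze the
        # chain block only
        frames = frames[:, : offsets[-1]]
    chain_id = _chain_id_from_offsets(offsets)
    n_chains = len(offsets) - 1
    if n_chains < 2:
        raise ValueError("mixing trace needs at least 2 chains")
    alphas, kept_times = [], []
    for f in range(frames.shape[0]):
        intra, inter = _count_intra_inter(
            np.ascontiguousarray(frames[f]), chain_id, float(cutoff),
            exclude_band,
        )
        if intra == 0 and inter > 0:
            continue  # alpha undefined for this frame; skip
        alphas.append(0.0 if inter == 0 else inter / intra)
        kept_times.append(times[f])
    alphas = np.asarray(alphas)
    kept_times = np.asarray(kept_times)
    n_tail = max(1, int(round(frame_window * len(alphas))))
    alpha_bar = float(alphas[-n_tail:].mean()) if len(alphas) else math.nan
    return MixingTrace(
        times=kept_times,
        alpha=alphas,
        alpha_max=float(n_chains - 1),
        alpha_bar=alpha_bar,
        window_fraction=frame_window,
    )


def contact_probability(frames, chain_offsets=None, cutoff=CONTACT_CUTOFF,
                        s_values=None):
    """Intra-chain contact probability P(s) versus contour separation.

    P(s) = (contacts at separation s) / (pairs at separation s), pooled over
    chains and frames; separations start at s = 2 (bonded neighbors are
    trivially in contact).  ``frames`` may be an array (F, N, 3) or an
    iterable of such arrays (batched ensembles).  Returns (s, P) with the
    separations for which at least one pair exists.
    """
    if isinstance(frames, np.ndarray) or hasattr(frames, "frames"):
        frames = [frames]
    first = True
    hits = totals = None
    for block in frames:
        block = _frames_of(block)
        if first:
            n = block.shape[1]
            if chain_offsets is None:
                chain_offsets = np.array([0, n])
            offsets = np.asarray(chain_offsets, dtype=np.int64)
            max_len = int(np.diff(offsets).max())
            if s_values is None:
                s_values = np.arange(2, max_len)
            s_values = np.asarray(s_values, dtype=np.int64)
            hits = np.zeros(len(s_values), np.int64)
            totals = np.zeros(len(s_values), np.int64)
            first = False
        for f in range(block.shape[0]):
            _ps_counts(np.ascontiguousarray(block[f]), offsets, s_values,
                       float(cutoff), hits, totals)
    if first:
        raise ValueError("no frames provided")
    ok = totals > 0
    return s_values[ok], hits[ok] / totals[ok]


def fit_power_law(x, y, window=None, two_regime=False, decay=False):
    """Least-squares power-law fit on log-log coordinates.

    Fits log y = a + b log x over the window; the reported exponent is -b
    for decays (P(s) ~ s^-gamma) and +b for growth laws (alpha ~ t^beta).
    With ``two_regime`` a continuous two-segment line is fitted, the
    breakpoint chosen by exhaustive search over interior grid points; the
    single-segment fit is kept unless the broken line cuts the squared
    residual by at least 20%.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if window is not None:
        lo, hi = window
        keep = (x >= lo) & (x <= hi)
        x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ValueError("power-law fit needs at least 5 points in the window")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive x and y")
    lx, ly = np.log(x), np.log(y)
    order = np.argsort(lx)
    lx, ly = lx[order], ly[order]
    sgn = -1.0 if decay else 1.0

    A1 = np.stack([np.ones_like(lx), lx], axis=1)
    coef1, res1, *_ = np.linalg.lstsq(A1, ly, rcond=None)
    pred1 = A1 @ coef1
    ssr1 = float(np.sum((ly - pred1) ** 2))
    sst = float(np.sum((ly - ly.mean()) ** 2))
    r2_single = 1.0 if sst == 0 else max(0.0, min(1.0, 1.0 - ssr1 / sst))
    single = ScalingFit(
        exponent=sgn * float(coef1[1]),
        prefactor=float(np.exp(coef1[0])),
        window=(float(np.exp(lx[0])), float(np.exp(lx[-1]))),
        r_squared=r2_single,
    )
    if not two_regime:
        return single

    best = None
    for k in range(2, len(lx) - 2):
        xb = lx[k]
        hinge = np.maximum(lx - xb, 0.0)
        A2 = np.stack([np.ones_like(lx), lx, hinge], axis=1)
        coef2, *_ = np.linalg.lstsq(A2, ly, rcond=None)
        ssr2 = float(np.sum((ly - A2 @ coef2) ** 2))
        if best is None or ssr2 < best[0]:
            best = (ssr2, xb, coef2)
    ssr2, xb, coef2 = best
    if ssr2 > 0.8 * ssr1:
        return single
    r2 = 1.0 if sst == 0 else max(0.0, min(1.0, 1.0 - ssr2 / sst))
    return ScalingFit(
        exponent=sgn * float(coef2[1]),
        prefactor=float(np.exp(coef2[0])),
        window=(float(np.exp(lx[0])), float(np.exp(lx[-1]))),
        r_squared=r2,
        breakpoint=float(np.exp(xb)),
        second_exponent=sgn * float(coef2[1] + coef2[2]),
    )


def _fit_final_segment(fit: ScalingFit):
    """(beta, alpha_at(t)) for the late-time segment of a mixing fit."""
    if fit.second_exponent is not None:
        beta = fit.second_exponent
        xb = fit.breakpoint

        def alpha_at(t):
            # continuous piecewise model evaluated past the breakpoint
            return fit.prefactor * xb ** fit.exponent * (t / xb) ** beta
    else:
        beta = fit.exponent

        def alpha_at(t):
            return fit.prefactor * t ** beta
    return beta, alpha_at


def extrapolate_mixing_time(trace: MixingTrace, fit: ScalingFit,
                            alpha_max=None, beta_floor=1e-3):
    """Extrapolate alpha ~ t^beta to the time of full mixing.

    t_mix = t_ref * (alpha_max / alpha(t_ref))^(1/beta) using the final
    fitted segment at the last trace time t_ref.  beta <= beta_floor means
    the chains never reach the ideal limit: returns +inf.
    """
    if alpha_max is None:
        alpha_max = trace.alpha_max
    t_ref = float(trace.times[-1])
    beta, alpha_at = _fit_final_segment(fit)
    a_ref = float(alpha_at(t_ref))
    if a_ref <= 0:
        raise ValueError("fitted alpha(t_ref) must be positive")
    if a_ref >= alpha_max:
        return t_ref
    if beta <= beta_floor:
        return math.inf
    return t_ref * (alpha_max / a_ref) ** (1.0 / beta)


def classify_mixing_state(t_mix, t_c=CRITICAL_TIME_TAU, beta=None):
    """Label a mixing time against the critical time t_c (~5 years).

    Returns a dict with the label (``mixes_within_tc`` when t_mix <= t_c,
    else ``rare_mixing``), the decade bin floor(log10 t_mix) clipped to
    [7, 16] for heat-map rendering, and, when beta is supplied, a flag for
    consistency with the observed exponent bands (mixing within t_c goes
    with beta in [1/8, 1/4]; slower mixing with beta < 1/8).
    """
    if not t_mix > 0:
        raise ValueError("t_mix must be positive (or +inf)")
    label = "mixes_within_tc" if t_mix <= t_c else "rare_mixing"
    decade = 16 if math.isinf(t_mix) else int(
        min(16, max(7, math.floor(math.log10(t_mix))))
    )
    out = {"label": label, "decade": decade}
    if beta is not None:
        fast_band = beta >= 1.0 / 8.0
        out["beta_band_consistent"] = (label == "mixes_within_tc") == fast_band
    return out


def write_mixing_grid(records, path):
    """State-diagram grid as TSV: phi, eps, beta, t_mix, decade per row.

    ``records`` is an iterable of dicts with those keys (e.g. assembled
    from mixing fits and :func:`classify_mixing_state` over a (phi, eps)
    sweep); used to serialize heat-map inputs.
    """
    cols = ["phi", "eps", "beta", "t_mix", "decade"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            fh.write("\t".join(f"{rec[c]:g}" for c in cols) + "\n")


def read_mixing_grid(path):
    """Read a state-diagram TSV written by :func:`write_mixing_grid`."""
    out = []
    with open(path) as fh:
        header = fh.readline().split()
        for line in fh:
            vals = [float(x) for x in line.split()]
            out.append(dict(zip(header, vals)))
    return out


def msd(trajectory, bead_subset=None, origin_mode="multiple", fit_window=None,
        decay=False, com_frame=False):
    """Mean-square displacement averaged over beads.

    origin_mode ``multiple`` averages over all time origins (FFT
    correlation algorithm); ``single`` measures from the first frame only.
    With ``com_frame`` displacements are measured relative to the center of
    mass of the selected beads — for short chains this removes the 6Dt/N
    whole-chain diffusion that otherwise contaminates the intermediate-time
    monomer subdiffusion regime.  Returns (lag_times, msd_values, fit)
    where the power-law fit covers ``fit_window`` (default: the central
    decade of available lags).
    """
    frames = _frames_of(trajectory)
    if frames.shape[0] < 10:
        raise ValueError("msd needs at least 10 frames")
    times = getattr(trajectory, "times", None)
    if times is None:
        times = np.arange(frames.shape[0], dtype=float)
    if bead_subset is None:
        bead_subset = np.arange(frames.shape[1])
    bead_subset = np.asarray(bead_subset)
    if len(bead_subset) == 0:
        raise ValueError("bead subset is empty")
    r = frames[:, bead_subset, :]
    if com_frame:
        r = r - r.mean(axis=1, keepdims=True)
    F = r.shape[0]
    dt_frame = float(np.mean(np.diff(times)))
    if origin_mode == "single":
        disp = r - r[0]
        vals = np.mean(np.sum(disp ** 2, axis=2), axis=1)
        lags = times - times[0]
        lags, vals = lags[1:], vals[1:]
    elif origin_mode == "multiple":
        vals = _msd_fft(r)
        lags = np.arange(1, F) * dt_frame
        vals = vals[1:]
    else:
        raise ValueError("origin_mode must be 'single' or 'multiple'")
    fit = None
    pos_ok = vals > 0
    if pos_ok.sum() >= 5:
        if fit_window is None:
            llo, lhi = np.log10(lags[pos_ok][0]), np.log10(lags[pos_ok][-1])
            mid = 0.5 * (llo + lhi)
            fit_window = (10 ** (mid - 0.5), 10 ** (mid + 0.5))
        try:
            fit = fit_power_law(lags[pos_ok], vals[pos_ok], window=fit_window,
                                decay=decay)
        except ValueError:
            fit = None
    return lags, vals, fit


def _msd_fft(r):
    """All-time-origin MSD via the FFT autocorrelation identity."""
    F, n, _ = r.shape
    nfft = 1 << (2 * F - 1).bit_length()
    sq = np.sum(r ** 2, axis=2)                       # (F, n)
    acf = np.zeros((F, n))
    for d in range(3):
        fw = np.fft.rfft(r[:, :, d], n=nfft, axis=0)
        acf += np.fft.irfft(fw * np.conj(fw), n=nfft, axis=0)[:F]
    counts = np.arange(F, 0, -1)[:, None]
    acf /= counts
    sumsq = np.cumsum(sq, axis=0)
    # S1(m) = sum_{k=m}^{F-1} sq[k] + sum_{k=0}^{F-1-m} sq[k]
    tail = sumsq[-1] - np.concatenate([np.zeros((1, n)), sumsq[:-1]], axis=0)
    head = sumsq[::-1]
    s1 = tail + head
    vals = s1 / counts - 2.0 * acf
    return np.mean(vals, axis=1)


def radius_of_gyration(positions, chain_id=None, per_chain=False):
    """Root-mean-square bead distance from the center of mass (sigma).

    With ``per_chain`` (requires chain_id) returns one R_g per chain.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 2:
        raise ValueError("radius of gyration needs at least 2 beads")
    if per_chain:
        if chain_id is None:
            raise ValueError("per_chain requires chain_id")
        chain_id = np.asarray(chain_id)
        out = []
        for c in np.unique(chain_id):
            sub = pos[chain_id == c]
            out.append(float(np.sqrt(np.mean(
                np.sum((sub - sub.mean(axis=0)) ** 2, axis=1)
            ))))
        return np.array(out)
    com = pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pos - com) ** 2, axis=1))))
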