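"""Fragment-coverage bias model.

Coverage is modelled at the level of *fragment sites* — potential fragments
identified by (reference sequence, start, length, strand).  The observed pair
count k_n at site n follows a negative binomial with mean

    mu_n = N * b_seq * b_len * b_GC(GC_n) * b_start,n * b_end,n

and dispersion r_n = mu_n / (alpha + beta * mu_n), giving the mean-variance
relationship sigma^2 = mu + alpha*mu + beta*mu^2 (alpha captures PCR/optical
duplication, beta its quadratic component; alpha = beta = 0 is the Poisson
limit).  The GC bias over 101 percent bins is exp of a natural cubic spline
with six knots; the flanking bias sums one parameter per nucleotide per
position -10..19 around the fragment start (120 parameters, shared with the
reverse-complemented end context) through twice the inverse logit:
b_start = 2 / (1 + exp(-sum_p b_{f,p}(start_p))).

Within one (sequence, fragment length) fit b_seq and b_len are constant and
absorbed into the normalisation, leaving 120 + 6 + 2 = 128 relevant
parameters.  Fits are run for a selected schedule of sequence/length
combinations and combined by (weighted) medians; the remaining sequence and
length biases are then obtained from corrected counts by alternating updates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

N_FLANK_POS = 30  # positions -10..19 relative to the fragment start
FLANK_OFFSET = 10
N_GC_BINS = 101
N_KNOTS = 6
NEUTRAL = 4  # context code for positions beyond the contig edge

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


# ---------------------------------------------------------------------------
# site feature container


@dataclass
class SiteData:
    """Vectorised fragment-site features for one (sequence, length) fit."""

    seq_id: str
    length: int
    gc: np.ndarray       # (n,) int GC percent 0..100
    fstart: np.ndarray   # (n, 30) uint8 codes, 4 = neutral
    fend: np.ndarray     # (n, 30) uint8 codes
    k: np.ndarray        # (n,) observed pair counts
    excluded: np.ndarray  # (n,) bool
    starts: np.ndarray | None = None
    strand: np.ndarray | None = None  # 0 = forward, 1 = reverse

    @property
    def n_sites(self) -> int:
        return len(self.gc)

    def kept(self) -> "SiteData":
        m = ~self.excluded
        return SiteData(
            self.seq_id, self.length, self.gc[m], self.fstart[m], self.fend[m],
            self.k[m], np.zeros(m.sum(), bool),
            None if self.starts is None else self.starts[m],
            None if self.strand is None else self.strand[m],
        )


def site_features(codes: np.ndarray, length: int, starts: np.ndarray):
    """GC percent and flank contexts for fragments of ``length`` at ``starts``.

    Flank positions outside the contig carry the neutral code and contribute
    no flank parameter.  The end context is reverse-complemented so position
    indices keep their meaning relative to the fragment.
    """
    codes = np.asarray(codes, dtype=np.uint8)
    L = len(codes)
    pad = np.full(L + 2 * FLANK_OFFSET + N_FLANK_POS, NEUTRAL, dtype=np.uint8)
    pad[FLANK_OFFSET : FLANK_OFFSET + L] = codes
    comp_pad = _COMP[pad]

    gc_cum = np.concatenate(([0], np.cumsum((codes == 1) | (codes == 2))))
    n_cum = np.concatenate(([0], np.cumsum(codes == 4)))
    gcount = gc_cum[starts + length] - gc_cum[starts]
    gc = np.floor(100.0 * gcount / length + 0.5).astype(np.int64)

    offs = np.arange(N_FLANK_POS)
    fstart = pad[starts[:, None] + offs[None, :]]
    ends = starts + length
    fend = comp_pad[(ends[:, None] + FLANK_OFFSET - 1 - offs[None, :]) + FLANK_OFFSET]
    return gc, fstart, fend


def all_sites(
    codes: np.ndarray,
    length: int,
    seq_id: str = "",
    k: np.ndarray | None = None,
    excluded: np.ndarray | None = None,
    both_strands: bool = False,
) -> SiteData:
    """Enumerate every fragment site of one length on one sequence."""
    L = len(codes)
    if length > L:
        starts = np.empty(0, dtype=np.int64)
    else:
        starts = np.arange(L - length + 1, dtype=np.int64)
    gc, fstart, fend = site_features(codes, length, starts)
    n = len(starts)
    if k is None:
        k = np.zeros(n)
    if excluded is None:
        excluded = np.zeros(n, dtype=bool)
    strand = np.zeros(n, dtype=np.uint8)
    sd = SiteData(seq_id, length, gc, fstart, fend, np.asarray(k, float),
                  np.asarray(excluded, bool), starts, strand)
    if both_strands:
        # the reverse-strand site at the same coordinates swaps start/end
        # contexts, leaving the bias product unchanged
        sd = SiteData(
            seq_id, length,
            np.concatenate([gc, gc]),
            np.concatenate([fstart, fend]),
            np.concatenate([fend, fstart]),
            np.concatenate([sd.k, np.zeros(n)]),
            np.concatenate([sd.excluded, sd.excluded]),
            np.concatenate([starts, starts]),
            np.concatenate([strand, np.ones(n, dtype=np.uint8)]),
        )
    return sd


# ---------------------------------------------------------------------------
# model components


@dataclass
class FlankParams:
    """120 flanking-bias parameters: 4 nucleotides x 30 positions."""

    table: np.ndarray = field(
        default_factory=lambda: np.zeros((4, N_FLANK_POS))
    )

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (4, N_FLANK_POS):
            raise ValueError("flank table must be 4 x 30")

    @property
    def n_parameters(self) -> int:
        return self.table.size

    def padded(self) -> np.ndarray:
        """5-row table whose neutral row contributes zero."""
        return np.vstack([self.table, np.zeros((1, N_FLANK_POS))])

    def centered(self) -> "FlankParams":
        """Per-position mean removed (reporting convention)."""
        return FlankParams(self.table - self.table.mean(axis=0, keepdims=True))


def flank_sums(params: FlankParams, contexts: np.ndarray) -> np.ndarray:
    pad = params.padded()
    return pad[contexts, np.arange(N_FLANK_POS)[None, :]].sum(axis=1)


def flank_bias(params: FlankParams, contexts: np.ndarray) -> np.ndarray:
    """b = 2 * inverse-logit of the summed position parameters."""
    return 2.0 * special.expit(flank_sums(params, contexts))


@dataclass
class GCSpline:
    """Natural cubic spline over GC percent; bias = exp(spline(GC)).

    Constant extrapolation beyond the outer knots; the outer knots sit on the
    extreme GC bins that contain counted fragments.
    """

    knots: np.ndarray   # (6,) strictly increasing bin positions
    values: np.ndarray  # (6,) spline values at the knots

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")

    def log_bias(self, gc=None) -> np.ndarray:
        if gc is None:
            gc = np.arange(N_GC_BINS)
        spl = CubicSpline(self.knots, self.values, bc_type="natural")
        x = np.clip(np.asarray(gc, float), self.knots[0], self.knots[-1])
        return spl(x)

    def bias(self, gc=None) -> np.ndarray:
        return np.exp(self.log_bias(gc))


def spline_basis(knots: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Matrix B with B @ values = natural-spline evaluation at ``x``."""
    knots = np.asarray(knots, float)
    xc = np.clip(np.asarray(x, float), knots[0], knots[-1])
    cols = []
    for j in range(len(knots)):
        e = np.zeros(len(knots))
        e[j] = 1.0
        cols.append(CubicSpline(knots, e, bc_type="natural")(xc))
    return np.column_stack(cols)


@dataclass
class Dispersion:
    """Two-parameter NB dispersion; (0, 0) signals the Poisson limit."""

    alpha: float = 0.0
    beta: float = 0.0

    def r(self, mu: np.ndarray) -> np.ndarray:
        denom = self.alpha + self.beta * np.asarray(mu, float)
        return np.where(denom > 0, mu / np.where(denom > 0, denom, 1.0), np.inf)

    def variance(self, mu: np.ndarray) -> np.ndarray:
        return mu + self.alpha * mu + self.beta * mu**2


# ---------------------------------------------------------------------------
# likelihoods


def site_mu(
    sites: SiteData, flank: FlankParams, gc_bias: np.ndarray, norm: float = 1.0
) -> np.ndarray:
    """Per-site NB mean N * b_GC * b_start * b_end (vectorised)."""
    bs = flank_bias(flank, sites.fstart)
    be = flank_bias(flank, sites.fend)
    return norm * gc_bias[sites.gc] * bs * be


def nb_loglik(
    k: np.ndarray, mu: np.ndarray, alpha: float, beta: float
) -> float:
    """Total NB log-likelihood; alpha = beta = 0 evaluates the Poisson limit."""
    k = np.asarray(k, float)
    mu = np.asarray(mu, float)
    if alpha < 0 or beta < 0:
        raise ValueError("negative dispersion parameters")
    if alpha == 0 and beta == 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(mu > 0, k * np.log(mu) - mu - special.gammaln(k + 1),
                          np.where(k == 0, 0.0, -np.inf))
        return float(ll.sum())
    r = mu / (alpha + beta * mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            special.gammaln(k + r) - special.gammaln(r) - special.gammaln(k + 1)
            + r * np.log(r / (r + mu)) + k * np.log(mu / (r + mu))
        )
        ll = np.where(mu > 0, ll, np.where(k == 0, 0.0, -np.inf))
    return float(ll.sum())


def _nb_ll_grad(k, mu, alpha, beta):
    """NB log-likelihood, d ll/d mu (per site) and d ll/d alpha, beta."""
    D = alpha + beta * mu
    r = mu / D
    rm = r + mu
    ll = (
        special.gammaln(k + r) - special.gammaln(r) - special.gammaln(k + 1)
        + r * np.log(r / rm) + k * np.log(mu / rm)
    )
    dll_dr = special.psi(k + r) - special.psi(r) + np.log(r) + 1 \
        - np.log(rm) - (r + k) / rm
    dll_dmu_at_r = k / mu - (r + k) / rm
    dr_dmu = alpha / D**2
    dll_dmu = dll_dmu_at_r + dll_dr * dr_dmu
    dll_da = float(np.sum(dll_dr * (-mu / D**2)))
    dll_db = float(np.sum(dll_dr * (-(mu**2) / D**2)))
    return float(ll.sum()), dll_dmu, dll_da, dll_db


# ---------------------------------------------------------------------------
# fit selection


def l80(genome) -> list[str]:
    """Minimal set of longest sequences jointly covering >= 80% of the genome."""
    lengths = sorted(
        ((genome.length(n), n) for n in genome.names), reverse=True
    )
    total = sum(l for l, _ in lengths)
    chosen, acc = [], 0
    for l, n in lengths:
        chosen.append(n)
        acc += l
        if acc >= 0.8 * total:
            break
    return chosen


def fits_per_sequence(n_sequences: int) -> int:
    """Schedule of fits per L80 sequence: 30 for one, 5 for >= 20, graded between."""
    return int(np.clip(round(60 / n_sequences), 5, 30))


def select_fits(genome, counts_by_seq_len: dict) -> list[tuple[str, int]]:
    """Pick the (sequence, fragment length) combinations to fit.

    ``counts_by_seq_len`` maps (seq_id, length) -> pair count.  For each L80
    sequence the schedule's number of fits is spread equally spaced over its
    thirty most abundant fragment lengths.
    """
    chosen_seqs = l80(genome)
    per_seq = fits_per_sequence(len(chosen_seqs))
    out: list[tuple[str, int]] = []
    for seq in chosen_seqs:
        lens = [(c, l) for (s, l), c in counts_by_seq_len.items()
                if s == seq and c > 0]
        lens.sort(key=lambda t: (-t[0], t[1]))
        top = [l for _, l in lens[:30]]
        if not top:
            continue
        n_pick = min(per_seq, len(top))
        idx = np.unique(np.round(np.linspace(0, len(top) - 1, n_pick)).astype(int))
        out.extend((seq, top[i]) for i in idx)
    if not out:
        raise ValueError("no counted pairs; cannot select bias fits")
    return out


# ---------------------------------------------------------------------------
# the three-step GC + flank fit


@dataclass
class FitResult:
    seq_id: str
    length: int
    flank: FlankParams
    spline: GCSpline
    gc_bias: np.ndarray          # (101,) renormalised bias values
    alpha: float
    beta: float
    sites_per_gc: np.ndarray     # (101,) site counts per GC bin
    converged: bool
    loglik: float = np.nan


class _FlankDesign:
    """Sparse one-hot design for the flank parameters of a site set.

    Row n of ``Xs`` selects the 120-vector entries (code * 30 + position)
    active in site n's start context; neutral positions contribute nothing.
    Flank sums and their gradients become sparse matrix-vector products.
    """

    def __init__(self, fstart: np.ndarray, fend: np.ndarray):
        from scipy import sparse

        def build(ctx):
            rr, cc = np.nonzero(ctx < 4)
            cols = ctx[rr, cc].astype(np.int64) * N_FLANK_POS + cc
            return sparse.csr_matrix(
                (np.ones(len(rr)), (rr, cols)),
                shape=(ctx.shape[0], 4 * N_FLANK_POS),
            )

        self.Xs = build(fstart)
        self.Xe = build(fend)

    def sums(self, x120: np.ndarray):
        return self.Xs @ x120, self.Xe @ x120

    def grad(self, ws: np.ndarray, we: np.ndarray) -> np.ndarray:
        return self.Xs.T @ ws + self.Xe.T @ we


def _fit_flank_poisson(sites: SiteData, g_per_site, flank0: FlankParams,
                       design: _FlankDesign):
    """Maximise the Poisson likelihood over flank params, per-bin GC fixed."""

    def negll(x):
        # parameter layout: x[c * 30 + p] for nucleotide c at position p
        ss, se = design.sums(x)
        bs = 2.0 * special.expit(ss)
        be = 2.0 * special.expit(se)
        mu = np.maximum(g_per_site * bs * be, 1e-300)
        ll = float(np.sum(sites.k * np.log(mu) - mu))
        w = sites.k - mu
        grad = design.grad(w * (1.0 - bs / 2.0), w * (1.0 - be / 2.0))
        return -ll, -grad

    res = optimize.minimize(
        negll, flank0.table.ravel(), jac=True, method="L-BFGS-B",
        bounds=[(-10, 10)] * 120, options={"maxiter": 200},
    )
    return FlankParams(res.x.reshape(4, N_FLANK_POS)), res


def _per_bin_gc_optimum(sites: SiteData, flank: FlankParams) -> np.ndarray:
    """Closed-form Poisson optimum of the free per-bin GC bias."""
    f = flank_bias(flank, sites.fstart) * flank_bias(flank, sites.fend)
    num = np.bincount(sites.gc, weights=sites.k, minlength=N_GC_BINS)
    den = np.bincount(sites.gc, weights=f, minlength=N_GC_BINS)
    g = np.zeros(N_GC_BINS)
    ok = den > 0
    g[ok] = num[ok] / den[ok]
    return g


def _fit_spline_values(knots, k_per_bin, f_per_bin, theta0):
    """Poisson fit of the six spline values with flank fixed (per-bin sums)."""
    bins = np.flatnonzero(f_per_bin > 0)
    B = spline_basis(np.asarray(knots, float), bins.astype(float))
    A = k_per_bin[bins]
    F = f_per_bin[bins]

    def negll(th):
        s = B @ th
        mu = F * np.exp(s)
        ll = float(np.sum(A * s - mu))
        grad = B.T @ (A - mu)
        return -ll, -grad

    res = optimize.minimize(
        negll, theta0, jac=True, method="L-BFGS-B",
        bounds=[(-20, 20)] * len(knots), options={"maxiter": 200},
    )
    return res.x, -res.fun


def _greedy_knots(k_per_bin, f_per_bin, sites_per_gc):
    """Greedy placement of the four inner knots (outer knots pinned).

    Starting from knots equally spaced in site counts, each round refits the
    spline for every single-knot move to the adjacent populated bin and keeps
    the best; stops when no move improves the Poisson likelihood.
    """
    populated = np.flatnonzero(k_per_bin > 0)
    if len(populated) < N_KNOTS:
        lo = populated[0] if len(populated) else 0
        hi = populated[-1] if len(populated) else 100
        knots = np.unique(np.linspace(max(lo - 2, 0), min(hi + 2, 100), N_KNOTS))
        while len(knots) < N_KNOTS:
            knots = np.append(knots, knots[-1] + 1)
        theta, ll = _fit_spline_values(knots, k_per_bin, f_per_bin,
                                       np.zeros(N_KNOTS))
        return knots, theta, ll
    lo, hi = populated[0], populated[-1]
    # equal spacing in cumulative site counts
    cum = np.cumsum(sites_per_gc)
    targets = np.linspace(0, cum[-1], N_KNOTS)[1:-1]
    inner = []
    for t in targets:
        cand = populated[np.argmin(np.abs(cum[populated] - t))]
        inner.append(cand)
    knots = np.array(sorted(set([lo] + inner + [hi])))
    while len(knots) < N_KNOTS:
        gaps = np.diff(knots)
        gi = int(np.argmax(gaps))
        mid_cands = populated[(populated > knots[gi]) & (populated < knots[gi + 1])]
        if len(mid_cands) == 0:
            extra = (knots[gi] + knots[gi + 1]) / 2.0
            knots = np.sort(np.append(knots, extra))
        else:
            knots = np.sort(np.append(knots, mid_cands[len(mid_cands) // 2]))

    def fit_at(kn, theta0):
        return _fit_spline_values(kn, k_per_bin, f_per_bin, theta0)

    g0 = np.zeros(N_GC_BINS)
    ok = f_per_bin > 0
    g0[ok] = np.clip(k_per_bin[ok] / f_per_bin[ok], 1e-8, None)
    theta0 = np.clip(np.log(np.maximum(
        np.interp(knots, np.flatnonzero(ok), g0[ok]), 1e-8)), -20, 20)
    theta, best_ll = fit_at(knots, theta0)
    for _round in range(50):
        improved = False
        for j in range(1, N_KNOTS - 1):
            for direction in (-1, 1):
                cands = populated[(populated > knots[j - 1]) & (populated < knots[j + 1])]
                pos = np.searchsorted(cands, knots[j])
                newpos = pos + direction
                if newpos < 0 or newpos >= len(cands) or cands[newpos] == knots[j]:
                    continue
                trial = knots.copy().astype(float)
                trial[j] = cands[newpos]
                th, ll = fit_at(trial, theta)
                if ll > best_ll + 1e-9:
                    knots, theta, best_ll = trial, th, ll
                    improved = True
        if not improved:
            break
    return knots.astype(float), theta, best_ll


def fit_gc_flank(
    sites: SiteData, min_sites: int = 10_000, max_nb_iter: int = 300
) -> FitResult | None:
    """Three-step GC + flanking-bias fit for one (sequence, length).

    Step 1: Poisson with a free per-bin GC bias (closed form) alternating
    with an L-BFGS flank fit.  Step 2: greedy six-knot natural-spline
    placement on the Poisson likelihood with the flank fixed.  Step 3: joint
    L-BFGS-B maximisation of the full negative-binomial likelihood (120 flank
    + 6 spline values + alpha + beta = 128 parameters) with knots fixed.
    """
    data = sites.kept()
    if data.n_sites < min_sites:
        logger.warning(
            "skipping fit %s len=%d: only %d usable sites",
            sites.seq_id, sites.length, data.n_sites,
        )
        return None
    if data.k.sum() == 0:
        logger.warning("skipping fit %s len=%d: all counts zero",
                       sites.seq_id, sites.length)
        return None

    # --- step 1: Poisson, flank + free per-bin GC
    design = _FlankDesign(data.fstart, data.fend)
    flank = FlankParams()
    g = _per_bin_gc_optimum(data, flank)
    for _ in range(4):
        flank, _res = _fit_flank_poisson(data, g[data.gc], flank, design)
        g_new = _per_bin_gc_optimum(data, flank)
        if np.allclose(g_new, g, rtol=1e-4, atol=1e-12):
            g = g_new
            break
        g = g_new
    flank = flank.centered()  # identifiability convention, before refinement
    g = _per_bin_gc_optimum(data, flank)

    # --- step 2: greedy knot placement on per-bin Poisson sums
    f = flank_bias(flank, data.fstart) * flank_bias(flank, data.fend)
    k_per_bin = np.bincount(data.gc, weights=data.k, minlength=N_GC_BINS)
    f_per_bin = np.bincount(data.gc, weights=f, minlength=N_GC_BINS)
    sites_per_gc = np.bincount(data.gc, minlength=N_GC_BINS).astype(float)
    knots, theta, _ll = _greedy_knots(k_per_bin, f_per_bin, sites_per_gc)

    # --- step 3: full NB likelihood over 128 parameters
    B_bins = spline_basis(knots, np.arange(N_GC_BINS, dtype=float))
    B_sites = B_bins[data.gc]

    def negll(x):
        th = x[120:126]
        alpha, beta = x[126], x[127]
        ss, se = design.sums(x[:120])
        bs = 2.0 * special.expit(ss)
        be = 2.0 * special.expit(se)
        gbias = np.exp(B_sites @ th)
        mu = np.maximum(gbias * bs * be, 1e-12)
        ll, dll_dmu, dll_da, dll_db = _nb_ll_grad(data.k, mu, alpha, beta)
        wmu = dll_dmu * mu
        gtheta = B_sites.T @ wmu
        gfl = design.grad(wmu * (1.0 - bs / 2.0), wmu * (1.0 - be / 2.0))
        grad = np.concatenate([gfl, gtheta, [dll_da, dll_db]])
        return -ll, -grad

    x0 = np.concatenate([flank.table.ravel(), theta, [0.1, 0.01]])
    bounds = [(-10, 10)] * 120 + [(-20, 20)] * 6 + [(1e-8, 1e5)] * 2
    res = optimize.minimize(
        negll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_nb_iter},
    )
    flank = FlankParams(res.x[:120].reshape(4, N_FLANK_POS))
    spline = GCSpline(knots, res.x[120:126])
    alpha, beta = float(res.x[126]), float(res.x[127])
    converged = bool(res.success) or res.status == 1  # maxiter hit still usable
    fit = FitResult(
        seq_id=sites.seq_id, length=sites.length, flank=flank, spline=spline,
        gc_bias=spline.bias(), alpha=alpha, beta=beta,
        sites_per_gc=sites_per_gc, converged=converged, loglik=float(-res.fun),
    )
    return renormalize_gc(fit)


def best_represented_bins(sites_per_gc: np.ndarray, frac: float = 0.8) -> np.ndarray:
    """Fewest GC bins with the most sites jointly covering >= frac of sites."""
    order = np.argsort(-sites_per_gc, kind="stable")
    cum = np.cumsum(sites_per_gc[order])
    need = frac * sites_per_gc.sum()
    n = int(np.searchsorted(cum, need) + 1)
    return np.sort(order[:n])


def renormalize_gc(fit: FitResult) -> FitResult:
    """Divide all 101 GC biases by their mean over the best-represented bins."""
    bins = best_represented_bins(fit.sites_per_gc)
    factor = fit.gc_bias[bins].mean()
    if factor > 0:
        fit.gc_bias = fit.gc_bias / factor
    return fit


# ---------------------------------------------------------------------------
# combining fits


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Smallest value whose cumulative normalised weight reaches 0.5."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    tot = w.sum()
    if tot <= 0:
        return float(np.median(v))
    cum = np.cumsum(w) / tot
    idx = int(np.searchsorted(cum, 0.5))
    return float(v[min(idx, len(v) - 1)])


def gc_weights(sites_per_gc: np.ndarray) -> np.ndarray:
    """Per-bin weights (sqrt(l)-1 spread by decaying distance), sum 1."""
    base = np.maximum(np.sqrt(sites_per_gc) - 1.0, 0.0)
    w = base.copy()
    for d in range(1, N_GC_BINS):
        decay = 10.0 ** (-d)
        if decay * base.max() < 1e-12 and d > 12:
            break
        w[d:] += base[:-d] * decay    # contribution from GC - d
        w[:-d] += base[d:] * decay    # contribution from GC + d
    s = w.sum()
    return w / s if s > 0 else w


@dataclass
class CombinedBias:
    """Median-combined bias model plus sequence/length biases."""

    flank: FlankParams
    gc_bias: np.ndarray                 # (101,)
    dispersion: Dispersion
    b_ref: dict = field(default_factory=dict)    # seq_id -> bias
    b_len: dict = field(default_factory=dict)    # fragment length -> bias


def combine_fits(fits: list[FitResult]) -> CombinedBias:
    """Combine per-(sequence, length) fits by medians.

    Flank parameters and dispersion use a plain median across fits; GC biases
    use a weighted median whose per-fit weights reflect how many sites inform
    each GC bin.
    """
    fits = [f for f in fits if f is not None and f.converged]
    if not fits:
        raise ValueError("no converged fits to combine")
    flank = FlankParams(np.median([f.flank.table for f in fits], axis=0))
    alpha = float(np.median([f.alpha for f in fits]))
    beta = float(np.median([f.beta for f in fits]))
    weights = np.array([gc_weights(f.sites_per_gc) for f in fits])
    biases = np.array([f.gc_bias for f in fits])
    gc = np.empty(N_GC_BINS)
    for b in range(N_GC_BINS):
        gc[b] = weighted_median(biases[:, b], weights[:, b])
    return CombinedBias(flank, gc, Dispersion(alpha, beta))


# ---------------------------------------------------------------------------
# bias sums and reference/length biases


@dataclass
class BiasSum:
    """Bias sums over all sites, sampled every 20th fragment length."""

    sampled_lengths: np.ndarray                  # (m,)
    per_ref: dict                                # seq_id -> (m,) exact sums
    max_site_bias: dict = field(default_factory=dict)  # seq_id -> (m,) maxima
    total: float = np.nan                        # simulation mode
    max_bias_by_len: dict = field(default_factory=dict)
    sum_by_len: dict = field(default_factory=dict)

    def b_sum(self, seq_id: str, length: int) -> float:
        i = int(np.argmin(np.abs(self.sampled_lengths - length)))
        return float(self.per_ref[seq_id][i])


def sampled_lengths(counts_by_len: dict, step: int = 20) -> np.ndarray:
    """Every ``step``-th length from the first non-zero count.

    Sampling stops at the first zero-count length unless stopping there would
    drop lengths carrying at least 10 counts.
    """
    lens = sorted(l for l, c in counts_by_len.items() if c > 0)
    if not lens:
        raise ValueError("no fragment length with non-zero count")
    first, last = lens[0], lens[-1]
    heavy = [l for l, c in counts_by_len.items() if c >= 10]
    out = []
    for l in range(first, last + 1, step):
        c = counts_by_len.get(l, 0)
        if c == 0 and not any(h >= l for h in heavy):
            break
        out.append(l)
    return np.array(out, dtype=int)


def exact_bias_sum(
    genome, combined: CombinedBias, length: int, exclusions=None
) -> dict:
    """Exact per-sequence sum (and max) of GC*flank biases over both strands."""
    out = {}
    for name in genome.names:
        codes = genome.codes(name)
        if length > len(codes):
            out[name] = (0.0, 0.0)
            continue
        starts = np.arange(len(codes) - length + 1, dtype=np.int64)
        gc, fs, fe = site_features(codes, length, starts)
        b = combined.gc_bias[gc] * flank_bias(combined.flank, fs) \
            * flank_bias(combined.flank, fe)
        if exclusions is not None:
            keep = ~exclusions.site_excluded(name, starts, length)
            b = b[keep]
        # the reverse-strand site swaps the two contexts: identical product
        out[name] = (2.0 * float(b.sum()), float(b.max(initial=0.0)))
    return out


def estimate_bias_sum(
    combined: CombinedBias,
    genome,
    counts_by_len: dict,
    mode: str = "simulation",
    exclusions=None,
) -> BiasSum:
    """Bias sums at sampled lengths plus per-mode interpolation.

    ``simulation`` mode interpolates the ratio bias-sum / length-bias with a
    natural spline through every sample, returning the total bias sum over
    all lengths and a per-length maximum-bias estimate.  ``training`` mode
    returns the exact sampled sums for the ref/length-bias iteration.
    """
    samples = sampled_lengths(counts_by_len)
    per_ref = {n: np.zeros(len(samples)) for n in genome.names}
    max_site = {n: np.zeros(len(samples)) for n in genome.names}
    for i, l in enumerate(samples):
        sums = exact_bias_sum(genome, combined, int(l), exclusions)
        for n, (s, mx) in sums.items():
            per_ref[n][i] = s
            max_site[n][i] = mx
    bs = BiasSum(samples, per_ref, max_site)
    if mode == "training":
        return bs

    # simulation mode: the full per-length bias sum is b_len(l) times the
    # (smooth) GC/flank/reference sum, so interpolate that ratio with every
    # sample as a knot and multiply the length bias back in
    lens = np.array(sorted(l for l, c in counts_by_len.items() if c > 0))
    b_len = np.array([combined.b_len.get(int(l), 0.0) for l in lens])
    samp_ratio = np.zeros(len(samples))
    for n in genome.names:
        bref = combined.b_ref.get(n, 1.0)
        samp_ratio += bref * per_ref[n]
    if len(samples) >= 2:
        ratio_spl = CubicSpline(samples, samp_ratio, bc_type="natural")
        ratios = ratio_spl(np.clip(lens, samples[0], samples[-1]))
    else:
        ratios = np.full(len(lens), samp_ratio[0] if len(samples) else 0.0)
    sums = np.maximum(ratios, 0.0) * b_len
    bs.sum_by_len = {int(l): float(s) for l, s in zip(lens, sums)}
    bs.total = float(sums.sum())
    max_ratio = 0.0
    for n in genome.names:
        bref = combined.b_ref.get(n, 1.0)
        max_ratio = max(max_ratio, float((bref * max_site[n]).max(initial=0.0)))
    bs.max_bias_by_len = {int(l): max_ratio * float(b)
                          for l, b in zip(lens, b_len)}
    return bs


def fit_ref_len_bias(
    summaries,
    bias_sum: BiasSum,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> tuple[dict, dict]:
    """Alternating updates of reference-sequence and fragment-length biases.

    Solves b_ref = C_ref / sum_len(b_len * b_sum) and the symmetric equation
    for b_len until the maximum relative change drops below ``tol``.  The
    scale degeneracy is fixed by making the count-weighted mean of b_len one.
    """
    refs = list(summaries.c_ref.keys())
    lens = np.asarray(bias_sum.sampled_lengths, dtype=int)
    c_ref = np.array([summaries.c_ref[r] for r in refs], float)
    c_len = np.array([summaries.c_len.get(int(l), 0) for l in lens], float)
    S = np.array([[bias_sum.per_ref[r][i] for i in range(len(lens))]
                  for r in refs])  # (n_ref, n_len)
    b_ref = np.where(c_ref > 0, 1.0, 0.0)
    b_len = np.where(c_len > 0, 1.0, 0.0)

    def normalise(br, bl):
        # fold the scale degeneracy: count-weighted mean of b_len equals one
        wsum = c_len.sum()
        if wsum > 0:
            scale = float((c_len * bl).sum() / wsum)
            if scale > 0:
                return br * scale, bl / scale
        return br, bl

    b_ref, b_len = normalise(b_ref, b_len)
    for _ in range(max_iter):
        denom_r = S @ b_len
        new_ref = np.where((denom_r > 0) & (c_ref > 0), c_ref / np.where(
            denom_r > 0, denom_r, 1.0), 0.0)
        denom_l = S.T @ new_ref
        new_len = np.where((denom_l > 0) & (c_len > 0), c_len / np.where(
            denom_l > 0, denom_l, 1.0), 0.0)
        new_ref, new_len = normalise(new_ref, new_len)
        rel = 0.0
        nz = new_ref > 0
        if nz.any():
            rel = max(rel, float(np.max(np.abs(new_ref[nz] - b_ref[nz])
                                        / new_ref[nz])))
        nz = new_len > 0
        if nz.any():
            rel = max(rel, float(np.max(np.abs(new_len[nz] - b_len[nz])
                                        / new_len[nz])))
        b_ref, b_len = new_ref, new_len
        if rel < tol:
            break
    ref_out = {r: float(b) for r, b in zip(refs, b_ref)}
    len_out = {int(l): float(b) for l, b in zip(lens, b_len)}
    return ref_out, len_out


def interpolate_len_bias(
    b_len_sampled: dict, counts_by_len: dict, n_knots: int = N_KNOTS
) -> dict:
    """Extend sampled length biases to all counted lengths.

    The count/bias ratio at the samples is nearly constant, so it is fitted
    with a natural spline whose knots are greedily reduced (dropping the knot
    whose removal increases the residual sum of squares least) until six
    remain; the spline then converts every length's count into a bias.
    """
    samples = np.array(sorted(l for l, b in b_len_sampled.items() if b > 0))
    if len(samples) == 0:
        return {}
    lens_all = np.array(sorted(l for l, c in counts_by_len.items() if c > 0))
    c_s = np.array([counts_by_len.get(int(l), 0) for l in samples], float)
    b_s = np.array([b_len_sampled[int(l)] for l in samples])
    ratio = np.where(b_s > 0, c_s / np.where(b_s > 0, b_s, 1.0), 0.0)
    if len(samples) <= 2:
        mean_ratio = ratio[ratio > 0].mean() if (ratio > 0).any() else 1.0
        return {int(l): counts_by_len[int(l)] / mean_ratio for l in lens_all}

    def ssr_for(knots):
        B = spline_basis(knots, samples.astype(float))
        coef, *_ = np.linalg.lstsq(B, ratio, rcond=None)
        resid = ratio - B @ coef
        return float(resid @ resid), coef

    knots = samples.astype(float).copy()
    best_ssr, coef = ssr_for(knots)
    while len(knots) > min(n_knots, len(samples)):
        cand = None
        for j in range(1, len(knots) - 1):
            trial = np.delete(knots, j)
            ssr, cf = ssr_for(trial)
            if cand is None or ssr < cand[0]:
                cand = (ssr, trial, cf)
        if cand is None:
            break
        best_ssr, knots, coef = cand[0], cand[1], cand[2]
    B_all = spline_basis(knots, np.clip(lens_all.astype(float),
                                        knots[0], knots[-1]))
    ratio_all = np.maximum(B_all @ coef, 1e-12)
    return {
        int(l): float(counts_by_len[int(l)] / r)
        for l, r in zip(lens_all, ratio_all)
    }
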