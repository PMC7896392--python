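"""Simulation: draw reads from a trained profile.

The generative order mirrors training: systematic error tendencies and rates
are first distributed over the template (per position and strand, sweeping
5'->3' with error-region bookkeeping), fragment counts per site are drawn
from the negative-binomial coverage model, and each fragment's two reads are
synthesised cycle by cycle — sequence quality, then a base-quality chain,
base calls and InDels — from the conditional distributions of the fitted
margin models.  Fragments shorter than the read length run into the mate's
adapter.  All randomness flows through one seeded generator, so identical
seeds give byte-identical FASTQ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .adapters import AdapterSet
from .covmodel import (
    CombinedBias, Dispersion, estimate_bias_sum, flank_bias, site_features,
)
from .genome import Genome, decode, encode, replace_n
from .margins import MarginSet, PairwiseExpModel
from .stats import (
    MAX_ERRORS_SO_FAR, dominant_window, gc_window_before, region_pos_bin,
    region_rate_bin,
)

logger = logging.getLogger(__name__)

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


# ---------------------------------------------------------------------------
# samplers


class Sampler:
    """Vectorised first-dimension conditional sampler over a fitted model.

    Raw condition values (quality scores, percent bins, cycles ...) are
    translated to the model's compressed/coarsened categories by
    nearest-observed-label lookup; draws come back on the raw scale.
    """

    def __init__(self, model: PairwiseExpModel, nominal_cards: list[int]):
        self.model = model
        self.nominal = list(nominal_cards)
        dims = model.margins.dims
        self.labels0 = np.asarray(
            dims[0].labels if dims[0].labels is not None
            else np.arange(dims[0].cardinality)
        )
        self.lookups = []
        for j in range(1, len(dims)):
            labels = np.asarray(
                dims[j].labels if dims[j].labels is not None
                else np.arange(dims[j].cardinality), dtype=float,
            )
            raw = np.arange(self.nominal[j])
            pos = np.searchsorted(labels, raw, side="left")
            pos = np.clip(pos, 0, len(labels) - 1)
            left = np.clip(pos - 1, 0, len(labels) - 1)
            use_left = np.abs(labels[left] - raw) <= np.abs(labels[pos] - raw)
            self.lookups.append(np.where(use_left, left, pos).astype(np.int64))
        cond = model.conditional_tensor()
        c0 = cond.shape[0]
        self._rest_shape = cond.shape[1:]
        self.cdf = np.cumsum(cond.reshape(c0, -1), axis=0)
        model._joint = None  # the CDF table is all sampling needs

    def draw_batch(self, cols: list[np.ndarray], u: np.ndarray) -> np.ndarray:
        idx = [
            lk[np.clip(np.asarray(c, dtype=np.int64), 0, len(lk) - 1)]
            for lk, c in zip(self.lookups, cols)
        ]
        flat = np.ravel_multi_index(idx, self._rest_shape) if self._rest_shape \
            else np.zeros(len(u), dtype=np.int64)
        sub = self.cdf[:, flat]
        picks = (sub < u[None, :]).sum(axis=0)
        picks = np.clip(picks, 0, len(self.labels0) - 1)
        return self.labels0[picks]

    def draw(self, fixed, rng: np.random.Generator):
        return self.draw_batch([np.array([v]) for v in fixed],
                               np.array([rng.random()]))[0]


class DegenerateSampler:
    """Always returns one value (used when a statistic saw no observations)."""

    def __init__(self, value=0):
        self.value = value

    def draw_batch(self, cols, u):
        n = len(u)
        return np.full(n, self.value)

    def draw(self, fixed, rng):
        return self.value


def make_sampler(ms: MarginSet, cell_cap: int, degenerate_value=0,
                 max_sweeps: int = 200, tol: float = 1e-3):
    if ms.total <= 0:
        return DegenerateSampler(degenerate_value)
    nominal = [d.cardinality for d in ms.dims]
    compressed = ms.compress()
    model = PairwiseExpModel(compressed, cell_cap=cell_cap,
                             dtype=np.float32).fit(
        max_sweeps=max_sweeps, tol=tol)
    return Sampler(model, nominal)


# ---------------------------------------------------------------------------
# profile bundle


@dataclass
class SimProfile:
    """Everything needed to simulate: bias model, samplers, adapters, lengths."""

    combined: CombinedBias
    samplers: dict                      # name -> Sampler; strata under tuple keys
    fragment_length_distribution: dict  # length -> probability
    adapter_set: AdapterSet | None
    read_length: int
    tiles: list[str] = field(default_factory=lambda: ["default"])
    max_qual: int = 42
    tendency_alphabet: int = 5

    def tile_probabilities(self) -> np.ndarray:
        return np.full(len(self.tiles), 1.0 / len(self.tiles))


# ---------------------------------------------------------------------------
# template error map


@dataclass
class TemplateErrorMap:
    """Systematic error tendencies/rates drawn onto a simulation template.

    Storable and reloadable so repeated runs share the same error positions,
    mirroring how real systematic errors persist between sequencing runs.
    """

    seq_names: list[str]
    read_length: int
    tendency: dict   # name -> (2, L) uint8, 4 = none, read orientation
    rate: dict       # name -> (2, L) float
    region_pos: dict
    region_rate: dict

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#read_length\t{self.read_length}\n")
            for name in self.seq_names:
                L = self.tendency[name].shape[1]
                fh.write(f"#sequence\t{name}\t{L}\n")
                for strand in (0, 1):
                    t = self.tendency[name][strand]
                    pos = np.flatnonzero(t < 4)
                    for p in pos:
                        fh.write(
                            f"{name}\t{strand}\t{p}\t{'ACGT'[t[p]]}\t"
                            f"{self.rate[name][strand, p]!r}\n"
                        )

    @classmethod
    def load(cls, path) -> "TemplateErrorMap":
        read_length = 100
        lens: dict[str, int] = {}
        rows: list[tuple] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#read_length"):
                    read_length = int(line.split("\t")[1])
                elif line.startswith("#sequence"):
                    _tag, name, L = line.rstrip("\n").split("\t")
                    lens[name] = int(L)
                elif line.strip():
                    name, strand, p, t, r = line.rstrip("\n").split("\t")
                    rows.append((name, int(strand), int(p), "ACGT".index(t),
                                 float(r)))
        em = cls(
            list(lens), read_length,
            {n: np.full((2, L), 4, np.uint8) for n, L in lens.items()},
            {n: np.zeros((2, L)) for n, L in lens.items()},
            {n: np.zeros((2, L), np.int32) for n, L in lens.items()},
            {n: np.zeros((2, L)) for n, L in lens.items()},
        )
        for name, strand, p, t, r in rows:
            em.tendency[name][strand, p] = t
            em.rate[name][strand, p] = r
        em.rebuild_regions()
        return em

    def rebuild_regions(self) -> None:
        """Deterministic region bookkeeping from tendencies and rates."""
        for name in self.seq_names:
            L = self.tendency[name].shape[1]
            for strand in (0, 1):
                direction = 1 if strand == 0 else -1
                t = self.tendency[name][strand]
                pos = np.flatnonzero(t < 4)
                order = np.argsort(pos if strand == 0 else -pos)
                rp = self.region_pos[name][strand]
                rr = self.region_rate[name][strand]
                rp[:] = 0
                rr[:] = 0.0
                reg_start, reg_rate = None, 0.0
                for p in pos[order]:
                    r = float(self.rate[name][strand, p])
                    inside = (
                        reg_start is not None
                        and 0 < (p - reg_start) * direction < self.read_length
                    )
                    if not inside or r > reg_rate:
                        reg_start, reg_rate = int(p), r
                        stop = reg_start + direction * self.read_length
                        span = np.arange(reg_start, np.clip(stop, -1, L),
                                         direction)
                        rp[span] = np.abs(span - reg_start)
                        rr[span] = reg_rate

    def equal(self, other: "TemplateErrorMap") -> bool:
        return all(
            np.array_equal(self.tendency[n], other.tendency[n])
            and np.allclose(self.rate[n], other.rate[n])
            for n in self.seq_names
        )


def _dominant_recent(history: list[int], none_code: int = 4) -> int:
    """Most frequent non-none code in the last five entries, ties to latest."""
    recent = history[-5:]
    counts = {}
    latest = {}
    for i, c in enumerate(recent):
        if c == none_code:
            continue
        counts[c] = counts.get(c, 0) + 1
        latest[c] = i
    if not counts:
        return none_code
    best = max(counts.values())
    cands = [c for c, k in counts.items() if k == best]
    return max(cands, key=lambda c: latest[c])


def draw_template_errors(
    template: Genome, profile: SimProfile, rng: np.random.Generator
) -> TemplateErrorMap:
    """Distribute systematic errors over the template.

    Sweeps each strand in sequencing direction, drawing a tendency (then a
    rate when the tendency is not "none") from the trained conditionals
    given the error-region position, the GC window before the base, the
    region-start rate, and the base context; each non-none draw opens a
    region of one read length, restarted early by a higher-rate draw.
    """
    rl = profile.read_length
    half = max(rl // 2, 1)
    tend_s = profile.samplers["tendency"]
    rate_s = profile.samplers["rate"]
    em = TemplateErrorMap(
        list(template.names), rl,
        {n: np.full((2, template.length(n)), 4, np.uint8) for n in template.names},
        {n: np.zeros((2, template.length(n))) for n in template.names},
        {n: np.zeros((2, template.length(n)), np.int32) for n in template.names},
        {n: np.zeros((2, template.length(n))) for n in template.names},
    )
    for name in template.names:
        codes = template.codes(name)
        L = len(codes)
        for strand in (0, 1):
            seq_codes = codes if strand == 0 else _COMP[codes[::-1]]
            gcb = gc_window_before(codes, strand, half)
            gcb_seq = gcb if strand == 0 else gcb[::-1]
            dom_ref = dominant_window(seq_codes[None, :], none_code=4)[0]
            t_out = em.tendency[name][strand]
            r_out = em.rate[name][strand]
            rp_out = em.region_pos[name][strand]
            rr_out = em.region_rate[name][strand]
            reg_start_i, reg_rate = None, 0.0
            tend_hist: list[int] = []
            us = rng.random((L, 2))
            for i in range(L):
                tpos = i if strand == 0 else L - 1 - i
                rel = 0 if reg_start_i is None else i - reg_start_i
                inside = reg_start_i is not None and 0 < rel < rl
                rpb = int(region_pos_bin(np.array([rel if inside else 0]), rl)[0])
                rrb = int(region_rate_bin(
                    np.array([reg_rate if inside else 0.0]),
                    np.array([rel if inside else 0]))[0])
                rb = int(seq_codes[i])
                if rb > 3:
                    tend_hist.append(4)
                    continue
                prev = int(seq_codes[i - 1]) if i > 0 else 4
                tend = int(tend_s.draw_batch(
                    [np.array([rpb]), np.array([gcb_seq[i]]), np.array([rrb]),
                     np.array([rb]), np.array([prev]),
                     np.array([int(dom_ref[i])])],
                    np.array([us[i, 0]]),
                )[0])
                if tend != 4 and tend != rb:
                    dom_err = _dominant_recent(tend_hist)
                    rate_pct = int(rate_s.draw_batch(
                        [np.array([rpb]), np.array([gcb_seq[i]]),
                         np.array([rrb]), np.array([rb]),
                         np.array([dom_err])],
                        np.array([us[i, 1]]),
                    )[0]) if not isinstance(rate_s, DegenerateSampler) else 0
                    rate = rate_pct / 100.0
                    if rate > 0:
                        t_out[tpos] = tend
                        r_out[tpos] = rate
                        if not inside or rate > reg_rate:
                            reg_start_i, reg_rate = i, rate
                        tend_hist.append(tend)
                    else:
                        tend_hist.append(4)
                else:
                    tend_hist.append(4)
                if inside:
                    rp_out[tpos] = rel
                    rr_out[tpos] = reg_rate
                elif reg_start_i == i:
                    rp_out[tpos] = 0
                    rr_out[tpos] = reg_rate
    return em


# ---------------------------------------------------------------------------
# site counts


def draw_site_counts(
    mu: np.ndarray, dispersion: Dispersion, rng: np.random.Generator
) -> np.ndarray:
    """Per-site NB draws with mean mu and dispersion r = mu/(alpha+beta*mu)."""
    mu = np.asarray(mu, float)
    if dispersion.alpha == 0 and dispersion.beta == 0:
        return rng.poisson(np.maximum(mu, 0.0))
    r = dispersion.r(mu)
    p = np.clip(r / (r + np.maximum(mu, 1e-300)), 1e-12, 1.0)
    out = np.zeros(len(mu), dtype=np.int64)
    ok = mu > 0
    out[ok] = rng.negative_binomial(np.maximum(r[ok], 1e-9), p[ok])
    return out


# ---------------------------------------------------------------------------
# read synthesis


@dataclass
class Fragments:
    """Vectorised fragment list: where each simulated pair comes from."""

    seq_idx: np.ndarray
    start: np.ndarray
    length: np.ndarray
    strand: np.ndarray
    allele: np.ndarray

    @property
    def n(self) -> int:
        return len(self.start)


def _dominant_cols(window: np.ndarray, none_code: int = 4) -> np.ndarray:
    """Dominant non-none code over a few trailing columns, ties to latest."""
    n, w = window.shape
    if w == 0:
        return np.full(n, none_code, np.uint8)
    counts = np.zeros((n, 4), np.int16)
    latest = np.full((n, 4), -1, np.int16)
    for j in range(w):
        col = window[:, j]
        for cde in range(4):
            hit = col == cde
            counts[hit, cde] += 1
            latest[hit, cde] = j
    maxc = counts.max(axis=1)
    score = counts.astype(np.int32) * (w + 1) + (latest + 1)
    score[counts < maxc[:, None]] = -1
    dom = np.argmax(score, axis=1).astype(np.uint8)
    return np.where(maxc > 0, dom, none_code).astype(np.uint8)


def synthesize_reads(
    fragments: Fragments,
    templates: list[Genome],     # one per allele
    error_maps: list[TemplateErrorMap],
    profile: SimProfile,
    rng: np.random.Generator,
):
    """Generate both reads of every fragment from the trained conditionals.

    Returns (bases1, quals1, bases2, quals2) as (n, read_length) arrays in
    sequencing orientation plus a per-read truth error mask per segment.
    """
    rl = profile.read_length
    n = fragments.n
    tile_idx = rng.integers(0, max(len(profile.tiles), 1), size=n)
    out = []
    for seg in (0, 1):
        read_strand = fragments.strand if seg == 0 else 1 - fragments.strand
        # per-read template window in read order (padded with adapter/fill)
        win = np.full((n, rl), 4, dtype=np.uint8)
        rate_pct = np.zeros((n, rl), dtype=np.int64)
        tend = np.full((n, rl), 4, dtype=np.uint8)
        for ai, (tmpl, emap) in enumerate(zip(templates, error_maps)):
            for si, name in enumerate(tmpl.names):
                sel = np.flatnonzero(
                    (fragments.allele == ai) & (fragments.seq_idx == si)
                )
                if len(sel) == 0:
                    continue
                codes = tmpl.codes(name)
                L = len(codes)
                st = fragments.start[sel]
                fl = fragments.length[sel]
                rs = read_strand[sel]
                cyc = np.arange(rl)[None, :]
                fwd = st[:, None] + cyc
                rev = (st + fl - 1)[:, None] - cyc
                pos = np.where(rs[:, None] == 0, fwd, rev)
                in_frag = cyc < np.minimum(fl, rl)[:, None]
                posc = np.clip(pos, 0, L - 1)
                t = codes[posc]
                t = np.where(rs[:, None] == 1, _COMP[t], t)
                win[sel] = np.where(in_frag, t, 4)
                r_em = emap.rate[name][rs[:, None] * np.ones(rl, int)[None, :], posc]
                t_em = emap.tendency[name][rs[:, None] * np.ones(rl, int)[None, :], posc]
                rate_pct[sel] = np.where(
                    in_frag, np.clip(np.floor(r_em * 100 + 0.5), 0, 100), 0
                ).astype(np.int64)
                tend[sel] = np.where(in_frag, t_em, 4)
        # adapter continuation beyond the fragment, then poly-A spacer
        short = fragments.length < rl
        if short.any() and profile.adapter_set is not None:
            adapters = profile.adapter_set.adapters(seg)
            acodes = encode(adapters[0])
            for ri in np.flatnonzero(short):
                tail = rl - fragments.length[ri]
                fill = np.zeros(tail, dtype=np.uint8)  # 0 == A
                fill[: len(acodes)] = acodes[:tail]
                win[ri, fragments.length[ri]:] = fill
        elif short.any():
            for ri in np.flatnonzero(short):
                tail = rl - fragments.length[ri]
                win[ri, fragments.length[ri]:] = rng.integers(0, 4, size=tail)

        # sequence quality
        read_gc = np.floor(
            100.0 * ((win == 1) | (win == 2)).sum(axis=1) / rl + 0.5
        ).astype(int)
        nvalid = np.minimum(fragments.length, rl).astype(float)
        mean_rate = np.floor(
            rate_pct.sum(axis=1) / np.maximum(nvalid, 1) + 0.5
        ).astype(int)
        flb = np.clip(fragments.length // 10, 0, 1000).astype(int)
        sq = profile.samplers["seq_quality"].draw_batch(
            [read_gc, mean_rate, flb, tile_idx, np.full(n, seg)],
            rng.random(n),
        ).astype(np.int64)

        quals = np.zeros((n, rl), dtype=np.int64)
        bases = np.zeros((n, rl), dtype=np.uint8)
        err = np.zeros((n, rl), dtype=bool)
        errors_so_far = np.zeros(n, dtype=np.int64)
        err_hist = np.full((n, rl), 4, dtype=np.uint8)
        prev_q = sq.copy()
        u_q = rng.random((n, rl))
        u_c = rng.random((n, rl))
        indel_s = profile.samplers.get("indel")
        indel_active = bool(profile.samplers.get("indel_active", False))
        tptr = np.arange(0)  # placeholder when indels are inactive
        if indel_active:
            tptr = np.zeros(n, dtype=np.int64)
            indel_pos = np.zeros(n, dtype=np.int64)
            indel_before = np.zeros(n, dtype=np.int64)
            last_call = win[:, 0].astype(np.int64) % 4
            u_i = rng.random((n, rl))
        for c in range(rl):
            if indel_active:
                evt = np.asarray(indel_s.draw_batch(
                    [np.clip(indel_pos, 0, rl - 1), np.full(n, c), read_gc,
                     last_call, np.clip(indel_before, 0, 1)],
                    u_i[:, c],
                ), dtype=np.int64)
                for _try in range(3):  # deletions consume template, redraw
                    dm = evt == 5
                    if not dm.any():
                        break
                    tptr[dm] += 1
                    indel_pos[dm] += 1
                    indel_before[dm] = 1
                    sub = np.flatnonzero(dm)
                    evt[sub] = np.asarray(indel_s.draw_batch(
                        [np.clip(indel_pos[sub], 0, rl - 1),
                         np.full(len(sub), c), read_gc[sub], last_call[sub],
                         np.ones(len(sub), np.int64)],
                        rng.random(len(sub)),
                    ), dtype=np.int64)
                evt[evt == 5] = 0
                ins = (evt >= 1) & (evt <= 4)
                rb = np.where(ins, evt - 1,
                              win[np.arange(n), np.clip(tptr, 0, rl - 1)]
                              ).astype(np.int64)
                rb[tptr >= rl] = 4
                rate_c = np.where(tptr < rl, rate_pct[
                    np.arange(n), np.clip(tptr, 0, rl - 1)], 0)
                tend_c = np.where(tptr < rl, tend[
                    np.arange(n), np.clip(tptr, 0, rl - 1)], 4)
            else:
                ins = np.zeros(n, dtype=bool)
                rb = win[:, c].astype(np.int64)
                rate_c = rate_pct[:, c]
                tend_c = tend[:, c]
            dom_err = _dominant_cols(err_hist[:, max(0, c - 5) : c]) \
                if c > 0 else np.full(n, 4, np.uint8)
            for ti in range(max(len(profile.tiles), 1)):
                for r in range(4):
                    sel = np.flatnonzero((rb == r) & (tile_idx == ti))
                    if len(sel) == 0:
                        continue
                    bq = np.asarray(profile.samplers["base_quality"][
                        (seg, ti, r)].draw_batch(
                        [sq[sel], prev_q[sel], np.full(len(sel), c),
                         rate_c[sel]],
                        u_q[sel, c],
                    ), dtype=np.int64)
                    quals[sel, c] = bq
                    call = np.asarray(profile.samplers["base_call"][
                        (seg, ti, r)].draw_batch(
                        [bq, np.full(len(sel), c),
                         np.clip(errors_so_far[sel], 0, MAX_ERRORS_SO_FAR),
                         rate_c[sel], dom_err[sel]],
                        u_c[sel, c],
                    ), dtype=np.int64)
                    t = tend_c[sel]
                    is_err = (call != r) & (call < 4)
                    # a systematic tendency decides the substituted base
                    final = np.where(is_err & (t < 4) & (t != r), t,
                                     np.clip(call, 0, 3)).astype(np.uint8)
                    final = np.where(call == 4, r, final).astype(np.uint8)
                    inssel = ins[sel]
                    final = np.where(inssel, r, final).astype(np.uint8)
                    bases[sel, c] = final
                    real_err = (final != r) & ~inssel
                    err[sel, c] = real_err
                    errors_so_far[sel] += real_err
                    err_hist[sel, c] = np.where(real_err, final, 4)
            sel_n = rb == 4  # fill cycles without template or adapter
            if sel_n.any():
                bases[sel_n, c] = rng.integers(0, 4, size=int(sel_n.sum()))
                quals[sel_n, c] = 2
            prev_q = quals[:, c].copy()
            if indel_active:
                tptr = tptr + (~ins).astype(np.int64)
                indel_pos = np.where(ins, indel_pos + 1, 0)
                indel_before = ins.astype(np.int64)
                last_call = bases[:, c].astype(np.int64) % 4
        out.append((bases, np.clip(quals, 0, profile.max_qual), err))
    return out


def write_fastq(path1, path2, names, reads1, reads2):
    """Write a mate-consistent FASTQ pair (Phred+33)."""
    b1, q1, _ = reads1
    b2, q2, _ = reads2
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i, name in enumerate(names):
            f1.write(f"@{name}\n{decode(b1[i])}\n+\n"
                     + "".join(chr(int(x) + 33) for x in q1[i]) + "\n")
            f2.write(f"@{name}\n{decode(b2[i])}\n+\n"
                     + "".join(chr(int(x) + 33) for x in q2[i]) + "\n")


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimulationResult:
    n_pairs: int
    fastq1: str
    fastq2: str
    truth_path: str
    error_map_paths: list[str]


def simulate(
    template: Genome,
    profile: SimProfile,
    out_prefix: str,
    seed: int,
    n_pairs: int | None = None,
    depth: float | None = None,
    alleles=None,
    abundance: dict | None = None,
    error_maps: list[TemplateErrorMap] | None = None,
    save_error_map: bool = False,
) -> SimulationResult:
    """End-to-end simulation to a FASTQ pair plus a truth sidecar TSV.

    Every fragment picks an allele fairly (diploid), a site proportionally to
    its bias, and a count from the NB model so that the expected total equals
    the requested number of pairs.
    """
    from .genome import apply_variants

    if (n_pairs is None) == (depth is None):
        raise ValueError("give exactly one of n_pairs or depth")
    rng = np.random.default_rng(seed)
    rl = profile.read_length
    template = replace_n(template, seed)
    if depth is not None:
        n_pairs = int(round(depth * template.total_length / (2 * rl)))

    if alleles is not None and alleles.ploidy == 2:
        templates = [apply_variants(template, alleles, a)[0] for a in (0, 1)]
    else:
        templates = [template]
    if error_maps is None:
        error_maps = [draw_template_errors(t, profile, rng) for t in templates]

    combined = profile.combined
    frag_dist = profile.fragment_length_distribution
    # fitted fragment-length biases when available, else the raw distribution
    blen = combined.b_len if combined.b_len else dict(frag_dist)
    lengths = sorted(l for l, p in blen.items() if p > 0 and l <= max(
        template.length(nm) for nm in template.names))
    b_ref = {}
    for nm in template.names:
        b = combined.b_ref.get(nm, 1.0)
        if abundance is not None:
            b *= abundance.get(nm, 1.0)
        b_ref[nm] = b

    # per-allele target
    per_allele = n_pairs / len(templates)
    frag_rows = []
    for ai, tmpl in enumerate(templates):
        counts_by_len = {l: frag_dist.get(l, blen[l]) for l in lengths}
        cb = CombinedBias(combined.flank, combined.gc_bias,
                          combined.dispersion, b_ref,
                          {l: blen[l] for l in lengths})
        bias_sum = estimate_bias_sum(cb, tmpl, counts_by_len,
                                     mode="simulation")
        total = bias_sum.total
        if total <= 0:
            raise ValueError("total bias sum is zero; nothing to simulate")
        for si, nm in enumerate(tmpl.names):
            codes = tmpl.codes(nm)
            L = len(codes)
            if b_ref[nm] == 0:
                continue
            for l in lengths:
                if l > L or blen[l] <= 0:
                    continue
                starts = np.arange(L - l + 1, dtype=np.int64)
                gc, fs, fe = site_features(codes, l, starts)
                b = combined.gc_bias[gc] * flank_bias(combined.flank, fs) \
                    * flank_bias(combined.flank, fe)
                b = b * b_ref[nm] * blen[l]
                mu = per_allele * b / total
                for strand in (0, 1):
                    k = draw_site_counts(mu, combined.dispersion, rng)
                    nz = np.flatnonzero(k)
                    for s_i in nz:
                        frag_rows.append(
                            (ai, si, int(starts[s_i]), l, strand, int(k[s_i]))
                        )

    if not frag_rows:
        raise ValueError("no fragments drawn; increase the target pair count")
    ALE, SI, ST, LN, SD, K = (np.array(x) for x in zip(*frag_rows))
    frag = Fragments(
        np.repeat(SI, K), np.repeat(ST, K), np.repeat(LN, K),
        np.repeat(SD, K), np.repeat(ALE, K),
    )
    order = rng.permutation(frag.n)
    frag = Fragments(frag.seq_idx[order], frag.start[order],
                     frag.length[order], frag.strand[order],
                     frag.allele[order])

    reads1, reads2 = synthesize_reads(frag, templates, error_maps, profile, rng)
    names = [
        f"rs:{templates[0].names[frag.seq_idx[i]]}:{frag.start[i]}:"
        f"{frag.start[i] + frag.length[i]}:{'+-'[frag.strand[i]]}:"
        f"{frag.allele[i]}:{i}"
        for i in range(frag.n)
    ]
    fq1 = f"{out_prefix}_1.fastq"
    fq2 = f"{out_prefix}_2.fastq"
    write_fastq(fq1, fq2, names, reads1, reads2)
    truth = f"{out_prefix}_truth.tsv"
    with open(truth, "w") as fh:
        fh.write("sequence\tstart\tend\tstrand\tallele\tpair_id\n")
        for i in range(frag.n):
            fh.write(
                f"{templates[0].names[frag.seq_idx[i]]}\t{frag.start[i]}\t"
                f"{frag.start[i] + frag.length[i]}\t{'+-'[frag.strand[i]]}\t"
                f"{frag.allele[i]}\t{i}\n"
            )
    em_paths = []
    if save_error_map:
        for ai, em in enumerate(error_maps):
            p = f"{out_prefix}_errors_allele{ai}.tsv"
            em.save(p)
            em_paths.append(p)
    return SimulationResult(frag.n, fq1, fq2, truth, em_paths)
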