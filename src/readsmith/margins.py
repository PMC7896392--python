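"""High-dimensional categorical statistics stored as two-dimensional margins.

A d-dimensional count matrix over quality/position/context variables is far
too large and too sparse to estimate directly, so only its C(d,2) pairwise
margins are kept.  For simulation the joint is reconstructed in a
pairwise-exponential form

    m_x = exp( sum over dimension pairs (a,b) of T_ab[x_a, x_b] )

whose pair terms absorb the overall level and the one-dimensional effects
(a Fienberg-style truncation of the interaction expansion at two dimensions);
the exponential guarantees positivity.  The terms are fitted by iterative
proportional fitting: each sweep enforces one stored margin at a time via the
multiplicative update m <- m * s_ij / (sum of m over the other dimensions),
which is additive on the pair term.  Conditional queries along the first
dimension only involve the terms containing that dimension, so the remaining
terms cancel in the normalisation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: cap on the dense outcome-space size used during fitting (DD: coarsen above)
DEFAULT_CELL_CAP = 10_000_000


@dataclass
class Dimension:
    """One categorical axis: a name, its cardinality, and optional labels.

    ``labels[i]`` is the original value that index ``i`` represents (used to
    translate raw observations into dense indices and back).
    """

    name: str
    cardinality: int
    labels: list | None = None

    def index_of(self, value) -> int:
        if self.labels is None:
            return int(value)
        return self.labels.index(value)


class MarginSet:
    """All pairwise margins of a d-dimensional count matrix."""

    def __init__(self, dims: list[Dimension]):
        if len(dims) < 2:
            raise ValueError("need at least two dimensions")
        self.dims = dims
        self.pairs = list(itertools.combinations(range(len(dims)), 2))
        self.tables = {
            (a, b): np.zeros((dims[a].cardinality, dims[b].cardinality))
            for a, b in self.pairs
        }
        self.total = 0.0

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return tuple(d.cardinality for d in self.dims)

    def accumulate(self, observations: np.ndarray, weights=None) -> None:
        """Add a batch of observations (integer array of shape (N, d))."""
        obs = np.asarray(observations, dtype=np.intp)
        if obs.ndim != 2 or obs.shape[1] != self.ndim:
            raise ValueError("observations must have shape (N, d)")
        cards = self.cardinalities
        for j in range(self.ndim):
            col = obs[:, j]
            if col.size and (col.min() < 0 or col.max() >= cards[j]):
                raise ValueError(f"coordinate out of range in dimension {j}")
        if weights is None:
            weights = 1.0
            self.total += obs.shape[0]
        else:
            weights = np.asarray(weights, dtype=float)
            self.total += float(weights.sum())
        for a, b in self.pairs:
            np.add.at(self.tables[(a, b)], (obs[:, a], obs[:, b]), weights)

    def compress(self) -> "MarginSet":
        """Drop categories never observed, recording original values as labels.

        Queries translate raw values through the labels; this keeps the dense
        outcome space small when nominal cardinalities (e.g. 101 GC bins) far
        exceed what the data populates.
        """
        seen = []
        for axis in range(self.ndim):
            m = self.one_dim_margin(axis)
            s = np.flatnonzero(m > 0)
            if len(s) == 0:
                s = np.array([0])
            seen.append(s)
        new_dims = []
        for d, s in zip(self.dims, seen):
            base_labels = d.labels if d.labels is not None else list(range(d.cardinality))
            new_dims.append(Dimension(d.name, len(s), [base_labels[i] for i in s]))
        out = MarginSet(new_dims)
        out.total = self.total
        for (a, b), t in self.tables.items():
            out.tables[(a, b)] = t[np.ix_(seen[a], seen[b])]
        return out

    def one_dim_margin(self, axis: int) -> np.ndarray:
        """The one-dimensional margin of ``axis`` from any pair containing it."""
        for (a, b), t in self.tables.items():
            if a == axis:
                return t.sum(axis=1)
            if b == axis:
                return t.sum(axis=0)
        raise ValueError(f"axis {axis} not present")

    def consistent(self, rtol: float = 1e-9) -> bool:
        """All pairs containing an axis imply the same one-dimensional margin."""
        for axis in range(self.ndim):
            ref = None
            for (a, b), t in self.tables.items():
                if axis == a:
                    m = t.sum(axis=1)
                elif axis == b:
                    m = t.sum(axis=0)
                else:
                    continue
                if ref is None:
                    ref = m
                elif not np.allclose(ref, m, rtol=rtol, atol=1e-9):
                    return False
        return True


def accumulate(dims: list[Dimension], observations) -> MarginSet:
    """Build a :class:`MarginSet` from a stream/array of d-tuples."""
    ms = MarginSet(dims)
    obs = np.asarray(list(observations) if not isinstance(observations, np.ndarray) else observations)
    if obs.size:
        ms.accumulate(obs)
    return ms


def _coarsen_margins(margins: MarginSet, cap: int) -> tuple[MarginSet, list[int]]:
    """Halve condition dimensions until the outcome space fits ``cap``.

    The first (drawn) dimension is only coarsened as a last resort, since its
    labels are what sampling returns.  Coarse bins are labelled by their
    middle member to avoid a systematic shift of drawn values.
    """
    factors = [1] * margins.ndim
    cards = list(margins.cardinalities)
    while np.prod([float(c) for c in cards]) > cap:
        rest = cards[1:]
        if rest and max(rest) > 2:
            w = 1 + int(np.argmax(rest))
        else:
            w = 0
        factors[w] *= 2
        cards[w] = (cards[w] + 1) // 2
    if all(f == 1 for f in factors):
        return margins, factors
    logger.info("coarsening dimensions by factors %s to fit the cell cap", factors)
    new_dims = []
    for j, (d, c) in enumerate(zip(margins.dims, cards)):
        base = d.labels if d.labels is not None else list(range(d.cardinality))
        labels = [
            base[min(i * factors[j] + factors[j] // 2, len(base) - 1)]
            for i in range(c)
        ]
        new_dims.append(Dimension(d.name, c, labels))
    out = MarginSet(new_dims)
    out.total = margins.total
    for (a, b), t in margins.tables.items():
        ca, cb = cards[a], cards[b]
        nt = np.zeros((ca, cb))
        ia = np.arange(t.shape[0]) // factors[a]
        ib = np.arange(t.shape[1]) // factors[b]
        np.add.at(nt, (ia[:, None], ib[None, :]), t)
        out.tables[(a, b)] = nt
    return out, factors


class PairwiseExpModel:
    """Fitted pairwise-exponential reconstruction of a :class:`MarginSet`."""

    def __init__(self, margins: MarginSet, cell_cap: int = DEFAULT_CELL_CAP,
                 dtype=np.float64):
        self.source = margins
        self.dtype = np.dtype(dtype)
        fit_margins, self.coarsening = _coarsen_margins(margins, cell_cap)
        self.margins = fit_margins
        self.dims = fit_margins.dims
        self.pairs = fit_margins.pairs
        self.terms = {
            p: np.zeros_like(fit_margins.tables[p]) for p in self.pairs
        }
        self.converged = False
        self.achieved_error = np.inf
        self._joint: np.ndarray | None = None

    # -- fitting -----------------------------------------------------------

    def _support_mask(self) -> np.ndarray:
        cards = self.margins.cardinalities
        mask = np.ones(cards, dtype=bool)
        for (a, b), t in self.margins.tables.items():
            shape = [1] * len(cards)
            shape[a], shape[b] = cards[a], cards[b]
            mask &= (t > 0).reshape(shape)
        return mask

    def fit(self, max_sweeps: int = 200, tol: float = 1e-3) -> "PairwiseExpModel":
        cards = self.margins.cardinalities
        nd = len(cards)
        mask = self._support_mask()
        m = mask.astype(self.dtype)
        if self.margins.total <= 0:
            raise ValueError("cannot fit a margin set with zero total")
        prev_err = np.inf
        stalled = 0
        for sweep in range(max_sweeps):
            max_err = 0.0
            for a, b in self.pairs:
                axes = tuple(i for i in range(nd) if i not in (a, b))
                cur = m.sum(axis=axes)
                s = self.margins.tables[(a, b)]
                ok = (s > 0) & (cur > 0)
                if ok.any():
                    err = float(np.max(np.abs(cur[ok] - s[ok]) / s[ok]))
                    max_err = max(max_err, err)
                ratio = np.ones_like(s, dtype=self.dtype)
                ratio[ok] = s[ok] / cur[ok]
                # cells where the model carries mass the margins forbid
                ratio[(s == 0) & (cur > 0)] = 0.0
                self.terms[(a, b)] += np.log(np.where(ratio > 0, ratio, 1.0))
                shape = [1] * nd
                shape[a], shape[b] = cards[a], cards[b]
                m = m * ratio.reshape(shape)
            if max_err < tol:
                self.converged = True
                self.achieved_error = max_err
                break
            # structural zeros can leave an irreducible margin mismatch;
            # stop once the error no longer shrinks meaningfully
            stalled = stalled + 1 if max_err > 0.95 * prev_err else 0
            prev_err = max_err
            if stalled >= 2:
                self.achieved_error = max_err
                logger.info(
                    "IPF stalled at margin error %.3g after %d sweeps",
                    max_err, sweep + 1,
                )
                break
        else:
            self.achieved_error = max_err
            logger.warning(
                "IPF did not reach tol=%g in %d sweeps (error %.3g)",
                tol, max_sweeps, max_err,
            )
        # canonical form (same arithmetic as deserialisation, so a saved and
        # reloaded model reproduces the joint bit-identically)
        log_m = np.zeros(cards)
        for (a, b), t in self.terms.items():
            shape = [1] * nd
            shape[a], shape[b] = cards[a], cards[b]
            log_m = log_m + t.reshape(shape)
        self._joint = np.where(mask, np.exp(log_m), 0.0)
        return self

    # -- evaluation --------------------------------------------------------

    def _map_fixed(self, fixed) -> tuple[int, ...]:
        if len(fixed) != len(self.dims) - 1:
            raise ValueError("fixed must give one value per dimension 2..d")
        return tuple(
            int(v) // self.coarsening[j + 1] for j, v in enumerate(fixed)
        )

    def joint(self) -> np.ndarray:
        """The fitted joint count tensor (same total as the margins)."""
        if self._joint is None:
            raise RuntimeError("call fit() first")
        return self._joint

    def margin_of(self, a: int, b: int) -> np.ndarray:
        nd = len(self.dims)
        axes = tuple(i for i in range(nd) if i not in (a, b))
        return self.joint().sum(axis=axes)

    def conditional(self, fixed) -> np.ndarray:
        """P(dim 1 | dims 2..d = fixed), a probability vector.

        Only the pair terms containing dimension 1 enter; the others cancel.
        An all-zero support slice falls back to the one-dimensional margin of
        dimension 1 (then uniform), with a log message.
        """
        fixed = self._map_fixed(fixed)
        card0 = self.dims[0].cardinality
        log_m = np.zeros(card0)
        alive = np.ones(card0, dtype=bool)
        for (a, b) in self.pairs:
            if a != 0:
                continue
            j = b - 1
            col = self.terms[(a, b)][:, fixed[j]]
            support = self.margins.tables[(a, b)][:, fixed[j]] > 0
            log_m += col
            alive &= support
        if not alive.any():
            marg = self.margins.one_dim_margin(0)
            if marg.sum() > 0:
                logger.debug("impossible fixed combination; marginal fallback")
                return marg / marg.sum()
            logger.debug("impossible fixed combination; uniform fallback")
            return np.full(card0, 1.0 / card0)
        p = np.where(alive, np.exp(log_m - log_m[alive].max()), 0.0)
        return p / p.sum()

    def conditional_tensor(self) -> np.ndarray:
        """P(dim 1 | rest) for every combination, shape = cardinalities.

        Zero-support slices get the dimension-1 marginal distribution.
        """
        joint = self.joint()
        denom = joint.sum(axis=0, keepdims=True)
        marg = self.margins.one_dim_margin(0)
        marg = marg / marg.sum() if marg.sum() > 0 else np.full(
            self.dims[0].cardinality, 1.0 / self.dims[0].cardinality
        )
        shape = [d.cardinality for d in self.dims]
        out = np.where(
            denom > 0,
            joint / np.where(denom > 0, denom, 1.0),
            marg.reshape([-1] + [1] * (len(shape) - 1)),
        )
        return out

    def draw(self, fixed, rng: np.random.Generator) -> int:
        """Inverse-CDF draw of dimension 1 given the other dimensions."""
        p = self.conditional(fixed)
        u = rng.random()
        return int(np.searchsorted(np.cumsum(p), u, side="right").clip(0, len(p) - 1))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "dims": [
                {"name": d.name, "cardinality": d.cardinality, "labels": d.labels}
                for d in self.margins.dims
            ],
            "coarsening": self.coarsening,
            "total": self.margins.total,
            "converged": self.converged,
            "achieved_error": self.achieved_error,
            "margins": {f"{a},{b}": t.tolist() for (a, b), t in self.margins.tables.items()},
            "terms": {f"{a},{b}": t.tolist() for (a, b), t in self.terms.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PairwiseExpModel":
        dims = [Dimension(x["name"], x["cardinality"], x["labels"]) for x in d["dims"]]
        ms = MarginSet(dims)
        ms.total = d["total"]
        for key, t in d["margins"].items():
            a, b = (int(x) for x in key.split(","))
            ms.tables[(a, b)] = np.array(t)
        model = cls.__new__(cls)
        model.source = ms
        model.margins = ms
        model.coarsening = list(d["coarsening"])
        model.dims = dims
        model.pairs = ms.pairs
        model.terms = {}
        for key, t in d["terms"].items():
            a, b = (int(x) for x in key.split(","))
            model.terms[(a, b)] = np.array(t)
        model.converged = d["converged"]
        model.achieved_error = d["achieved_error"]
        model._joint = None
        # rebuild the dense joint from terms and support
        cards = ms.cardinalities
        nd = len(cards)
        mask = model._support_mask()
        log_m = np.zeros(cards)
        for (a, b), t in model.terms.items():
            shape = [1] * nd
            shape[a], shape[b] = cards[a], cards[b]
            log_m = log_m + t.reshape(shape)
        model._joint = np.where(mask, np.exp(log_m), 0.0)
        return model


def ipf_fit(
    margins: MarginSet, max_sweeps: int = 200, tol: float = 1e-3,
    cell_cap: int = DEFAULT_CELL_CAP,
) -> PairwiseExpModel:
    """Fit the pairwise-exponential model to a margin set by IPF."""
    return PairwiseExpModel(margins, cell_cap=cell_cap).fit(max_sweeps, tol)
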