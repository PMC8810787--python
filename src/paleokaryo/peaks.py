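"""Peak detection on Ks / similarity distributions and topology scanning.

Peaks of the Ks distribution of syntenic homolog pairs mark speciation
(ortholog pairs) and whole-genome-duplication (paralog pairs) events.  The
topology scan enumerates every rooted binary topology on the sampled taxa
and keeps those on which the peak modes are consistent with the nesting:
values assigned to an ancestral node must precede (greater Ks, or lower
similarity) or overlap those of its descendant nodes, and peaks mapped to
the same node must mutually overlap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

MIN_VALUES = 30
DEFAULT_MIN_MASS = 0.05
MAX_LEAVES = 8  # (2n-3)!! enumeration explodes beyond this


@dataclass
class Peak:
    mode: float
    lo: float
    hi: float
    mass: float

    def overlaps(self, other: "Peak") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi


@dataclass
class PeakSet:
    axis: str  # "ks" | "similarity"
    peaks: list[Peak]
    n: int

    @property
    def primary(self) -> Peak:
        return max(self.peaks, key=lambda p: p.mass)


@dataclass
class TopologyVerdict:
    newick: str
    consistent: bool
    violations: list[str] = field(default_factory=list)


def estimate_peaks(values, axis: str = "ks",
                   bandwidth: float | None = None,
                   min_mass: float = DEFAULT_MIN_MASS,
                   grid_size: int = 2048) -> PeakSet:
    """Find modes of a Ks or similarity distribution by Gaussian KDE.

    Local density maxima holding at least ``min_mass`` of the total mass
    (mass = integral over the basin between flanking minima) become peaks;
    each peak's interval is the contiguous half-height span around its mode.
    ``bandwidth`` is an absolute kernel bandwidth on the axis scale;
    ``None`` uses Silverman's rule.
    """
    values = np.asarray(values, dtype=float)
    if values.size < MIN_VALUES:
        raise ValueError(
            f"need >= {MIN_VALUES} values for peak estimation, got "
            f"{values.size}; pool more pairs")
    if np.ptp(values) == 0.0:
        v = float(values[0])
        return PeakSet(axis=axis, peaks=[Peak(mode=v, lo=v, hi=v, mass=1.0)],
                       n=values.size)

    sd = values.std(ddof=1)
    bw = None if bandwidth is None else bandwidth / sd
    kde = gaussian_kde(values, bw_method=bw)
    h = kde.factor * sd
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, grid_size)
    dens = kde(grid)

    maxima = list(argrelextrema(dens, np.greater)[0])
    minima = list(argrelextrema(dens, np.less)[0])
    if not maxima:
        maxima = [int(np.argmax(dens))]
    boundaries = [0] + minima + [grid_size - 1]

    peaks = []
    for m in maxima:
        lo_b = max(b for b in boundaries if b <= m)
        hi_b = min(b for b in boundaries if b >= m)
        mass = float(np.trapezoid(dens[lo_b:hi_b + 1], grid[lo_b:hi_b + 1]))
        if mass < min_mass:
            continue
        half = dens[m] / 2.0
        lo = m
        while lo > lo_b and dens[lo - 1] >= half:
            lo -= 1
        hi = m
        while hi < hi_b and dens[hi + 1] >= half:
            hi += 1
        peaks.append(Peak(mode=float(grid[m]), lo=float(grid[lo]),
                          hi=float(grid[hi]), mass=mass))
    peaks.sort(key=lambda p: p.mode)
    return PeakSet(axis=axis, peaks=peaks, n=values.size)


# ---------------------------------------------------------------------------
# rooted binary topology enumeration
# ---------------------------------------------------------------------------

def enumerate_rooted_topologies(leaves: list[str]):
    """All rooted binary topologies on ``leaves``, as nested tuples.

    There are (2n-3)!! of them; n is capped at 8.
    """
    leaves = sorted(leaves)
    if len(leaves) > MAX_LEAVES:
        raise ValueError(f"at most {MAX_LEAVES} leaves supported")
    if len(leaves) == 1:
        return [leaves[0]]
    trees = [leaves[0]]
    for leaf in leaves[1:]:
        trees = [t for tree in trees for t in _insert_leaf(tree, leaf)]
    return trees


def _insert_leaf(tree, leaf):
    # graft on the root edge
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for sub in _insert_leaf(left, leaf):
            yield (sub, right)
        for sub in _insert_leaf(right, leaf):
            yield (left, sub)


def topology_newick(tree) -> str:
    def fmt(t):
        if isinstance(t, tuple):
            return "(" + ",".join(fmt(c) for c in t) + ")"
        return t
    return fmt(tree) + ";"


def double_factorial(m: int) -> int:
    out = 1
    while m > 1:
        out *= m
        m -= 2
    return out


# ---------------------------------------------------------------------------
# trees in the peaks
# ---------------------------------------------------------------------------

def _clades(tree) -> list[tuple[frozenset, frozenset, frozenset]]:
    """(node leaves, left leaves, right leaves) for every internal node."""
    out = []

    def walk(t) -> frozenset:
        if not isinstance(t, tuple):
            return frozenset((t,))
        left, right = (walk(c) for c in t)
        out.append((left | right, left, right))
        return left | right

    walk(tree)
    return out


def trees_in_peaks(leaves: list[str],
                   pair_peaks: dict[frozenset, PeakSet],
                   axis: str = "ks",
                   paralog_peaks: dict[str, PeakSet] | None = None
                   ) -> list[TopologyVerdict]:
    """Filter all rooted binary topologies by the precede-or-overlap rule.

    Every leaf pair's primary peak is attached to the internal node that is
    the pair's most recent common ancestor; a node's value is the
    mass-weighted mean of its attached modes and its interval the union span.
    A topology is consistent iff (a) the peaks attached to each node
    mutually overlap and (b) every ancestral node precedes (greater Ks /
    lower similarity) or overlaps each of its descendant nodes.

    ``paralog_peaks`` optionally maps a leaf to its within-genome (WGD)
    peak set; each such peak must then be younger than (or overlap) the
    divergence value of every node above that leaf — a lineage-specific
    duplication postdates the lineage's origin.  Off by default: the
    topology signal lives in the speciation peaks.
    """
    if axis not in ("ks", "similarity"):
        raise ValueError(f"unknown axis {axis!r}")
    for pair in itertools.combinations(sorted(leaves), 2):
        if frozenset(pair) not in pair_peaks:
            raise ValueError(f"missing peak set for leaf pair {pair}")

    older = ((lambda a, d: a >= d) if axis == "ks"
             else (lambda a, d: a <= d))

    verdicts = []
    for tree in enumerate_rooted_topologies(list(leaves)):
        clades = _clades(tree)
        node_peaks: dict[frozenset, list[Peak]] = {c[0]: [] for c in clades}
        for clade, left, right in clades:
            for a in left:
                for b in right:
                    node_peaks[clade].append(
                        pair_peaks[frozenset((a, b))].primary)

        violations = []
        node_val: dict[frozenset, tuple[float, float, float]] = {}
        for clade, _, _ in clades:
            pk = node_peaks[clade]
            for p, q in itertools.combinations(pk, 2):
                if not p.overlaps(q):
                    violations.append(
                        f"node {sorted(clade)}: peaks at {p.mode:.3g} and "
                        f"{q.mode:.3g} do not overlap")
            wsum = sum(p.mass for p in pk) or 1.0
            mode = sum(p.mode * p.mass for p in pk) / wsum
            node_val[clade] = (mode, min(p.lo for p in pk),
                               max(p.hi for p in pk))

        for anc, _, _ in clades:
            for dec, _, _ in clades:
                if dec is anc or not dec < anc:
                    continue
                (am, alo, ahi), (dm, dlo, dhi) = node_val[anc], node_val[dec]
                if not (older(am, dm) or (alo <= dhi and dlo <= ahi)):
                    violations.append(
                        f"ancestor {sorted(anc)} ({am:.3g}) younger than "
                        f"descendant {sorted(dec)} ({dm:.3g})")

        for leaf, pset in (paralog_peaks or {}).items():
            for clade, _, _ in clades:
                if leaf not in clade:
                    continue
                am, alo, ahi = node_val[clade]
                for p in pset.peaks:
                    if not (older(am, p.mode) or (alo <= p.hi
                                                  and p.lo <= ahi)):
                        violations.append(
                            f"WGD peak of {leaf} ({p.mode:.3g}) older than "
                            f"ancestor {sorted(clade)} ({am:.3g})")
        verdicts.append(TopologyVerdict(
            newick=topology_newick(tree),
            consistent=not violations, violations=violations))
    return verdicts
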