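"""Extended-haplotype-homozygosity statistics on phased haplotype panels.

The substrate is a binary haplotype-by-site matrix (phased genotypes, derived
allele coded 1). From it we compute, per core site:

* EHH — the probability that two randomly drawn haplotypes carrying the same
  core allele are identical-by-state from the core out to a given distance,
  ``EHH(t) = sum_h C(c_h, 2) / C(n_a, 2)`` where ``c_h`` counts carriers
  sharing extended haplotype ``h`` and ``n_a`` is the carrier count;
* iHH — the trapezoidal integral of the EHH decay curve against physical
  distance (bp), summed over the left and right arms;
* unstandardized iHS — ``ln(iHH_ancestral / iHH_derived)``;
* SL — the mean, over carrier pairs, of the number of consecutive sites
  (inclusive of the core) over which the pair is identical; and
  unstandardized nSL — ``ln(SL_ancestral / SL_derived)``.

Raw scores are standardized within derived-allele-frequency bins so that
scores are comparable across frequencies; large negative standardized values
mark unusually long derived-allele haplotypes (recent positive selection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .variants import VariantRecord

__all__ = [
    "HaplotypeMatrix",
    "EhhCurve",
    "SiteScore",
    "StandardizedScore",
    "ScanConfig",
    "ehh_curve",
    "ihh",
    "ihs_unstandardized",
    "sl_statistic",
    "nsl_unstandardized",
    "standardize",
]


@dataclass
class HaplotypeMatrix:
    """Binary phased haplotype panel: ``alleles[h, s]`` is haplotype h's allele
    at site s (0 = ancestral, 1 = derived); ``positions`` are strictly
    increasing bp coordinates."""

    alleles: np.ndarray  # (n_hap, n_site) of {0, 1}
    positions: np.ndarray  # (n_site,) strictly increasing ints, bp
    chrom: str = "1"
    #: founder haplotypes when the panel came from the simulator; ignored by
    #: every statistic
    founders: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotype-by-site array")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length must equal the site count")
        if self.n_hap < 4:
            raise ValueError("need at least 4 haplotypes")
        if not np.all(np.isin(self.alleles, (0, 1))):
            raise ValueError("alleles must be 0/1 with no missing entries")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_site(self) -> int:
        return self.alleles.shape[1]

    def daf(self, site: int) -> float:
        """Derived allele frequency at a site."""
        return float(self.alleles[:, site].mean())

    @classmethod
    def from_records(
        cls, records: Sequence[VariantRecord], samples: Sequence[str]
    ) -> "HaplotypeMatrix":
        """Build a panel from phased biallelic records (2 haplotypes/sample).

        Sites with any missing allele are dropped: the haplotype statistics
        require a complete matrix.
        """
        cols = []
        positions = []
        chrom = None
        for rec in records:
            if not rec.is_biallelic:
                raise ValueError("split multiallelic records before building a panel")
            if not rec.phased:
                raise ValueError(f"{rec.chrom}:{rec.pos}: unphased record")
            if chrom is None:
                chrom = rec.chrom
            elif rec.chrom != chrom:
                raise ValueError("panel must be single-chromosome")
            col = []
            missing = False
            for s in samples:
                gt = rec.genotypes.get(s, (None, None))
                if gt[0] is None or gt[1] is None:
                    missing = True
                    break
                col.extend(gt)
            if not missing:
                cols.append(col)
                positions.append(rec.pos)
        if not cols:
            raise ValueError("no complete phased sites")
        return cls(
            alleles=np.array(cols, dtype=np.int8).T,
            positions=np.array(positions),
            chrom=chrom or "1",
        )


@dataclass
class EhhCurve:
    """EHH decay on both arms of a core site.

    Each arm is an (m, 2) array of (distance bp, EHH value) starting at
    (0, 1.0); the arm stops at the first point where EHH drops below the
    cutoff (that point is included) or at the chromosome edge.
    """

    left: np.ndarray
    right: np.ndarray
    n_carriers: int
    #: arm hit the chromosome edge with EHH still >= cutoff
    edge_left: bool
    edge_right: bool

    @property
    def reached_edge(self) -> bool:
        return self.edge_left or self.edge_right


@dataclass
class SiteScore:
    site_index: int
    pos: int
    daf: float
    raw: float  # ln(iHH_A/iHH_D) or ln(SL_A/SL_D); nan when invalid
    metric: str  # "ihs" | "nsl"
    valid: bool


@dataclass
class StandardizedScore(SiteScore):
    z: float = math.nan
    bin_index: int = -1


@dataclass
class ScanConfig:
    """Parameters of the haplotype scan.

    ehh_cutoff: EHH level at which arm integration stops (0.05, the common
        tool default). truncation_policy "skip" invalidates cores whose EHH
        never decays below the cutoff before the chromosome edge; "clip"
        integrates to the edge (useful on short synthetic chromosomes).
    n_daf_bins / min_bin_count: equal-width derived-allele-frequency bins for
        standardization, small bins merged with a neighbour.
    maf_floor: minimum minor allele frequency for a scorable core site,
        matching the cohort variant filter.
    """

    ehh_cutoff: float = 0.05
    n_daf_bins: int = 50
    min_bin_count: int = 20
    maf_floor: float = 0.05
    truncation_policy: str = "skip"

    def __post_init__(self) -> None:
        if not (0 < self.ehh_cutoff < 1):
            raise ValueError("ehh_cutoff must be in (0, 1)")
        if self.truncation_policy not in ("skip", "clip"):
            raise ValueError("truncation_policy must be 'skip' or 'clip'")


def _pairs(n: int) -> int:
    return n * (n - 1) // 2


def _adjacent_lcp(seg: np.ndarray) -> np.ndarray:
    """Shared-prefix lengths between lexicographically adjacent carrier rows.

    ``seg`` holds one arm of the carriers' haplotypes, nearest site first.
    """
    n, width = seg.shape
    seg = np.ascontiguousarray(seg)
    keys = seg.view(np.dtype((np.void, seg.dtype.itemsize * width))).ravel()
    order = np.argsort(keys)
    s = seg[order]
    neq = s[1:] != s[:-1]
    any_neq = neq.any(axis=1)
    return np.where(any_neq, neq.argmax(axis=1), width)


def _arm_ehh_profile(
    alleles: np.ndarray, carriers: np.ndarray, core: int, step: int
) -> np.ndarray:
    """Carrier pairs identical through every extension distance t = 1..edge.

    ``EHH(t)`` is this count divided by ``C(n, 2)``. A pair is identical through t sites iff the minimum
    adjacent shared-prefix length over the lexicographically sorted span
    between them is >= t, so the whole profile follows from the adjacent-LCP
    array by accumulating union-find merges in decreasing LCP order.
    """
    n_site = alleles.shape[1]
    if step > 0:
        seg = alleles[carriers, core + 1 :]
    else:
        seg = alleles[carriers, :core][:, ::-1]
    width = seg.shape[1]
    n = carriers.size
    if width == 0 or n < 2:
        return np.zeros(0, dtype=np.int64)
    lcp = _adjacent_lcp(seg)
    # union-find over sorted rows; a merge at LCP value L contributes
    # size_a * size_b identical pairs at every t <= L
    parent = list(range(n))
    size = [1] * n

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    contrib = np.zeros(width + 1, dtype=np.int64)  # contrib[L] at index L
    for i in np.argsort(-lcp, kind="stable"):
        L = int(lcp[i])
        if L == 0:
            break
        a, b = find(i), find(i + 1)
        contrib[L] += size[a] * size[b]
        parent[a] = b
        size[b] += size[a]
    return np.cumsum(contrib[::-1])[::-1][1:]  # pairs identical through t


def _arm(
    alleles: np.ndarray,
    positions: np.ndarray,
    carriers: np.ndarray,
    core: int,
    step: int,
    cutoff: float,
) -> tuple[np.ndarray, bool]:
    """One arm of the EHH decay curve.

    Returns (distance bp, EHH) points — starting at (0, 1) and truncated at
    the first point with EHH < cutoff (included) — plus whether the
    chromosome edge was reached with EHH still >= cutoff.
    """
    denom = _pairs(carriers.size)
    profile = _arm_ehh_profile(alleles, carriers, core, step) / denom
    below = np.flatnonzero(profile < cutoff)
    if below.size:
        edge = False
        profile = profile[: below[0] + 1]
    else:
        edge = True
    t = np.arange(1, profile.size + 1)
    dist = np.abs(
        positions[core + step * t].astype(np.int64) - int(positions[core])
    ).astype(np.float64)
    pts = np.empty((profile.size + 1, 2))
    pts[0] = (0.0, 1.0)
    pts[1:, 0] = dist
    pts[1:, 1] = profile
    return pts, edge


def ehh_curve(
    matrix: HaplotypeMatrix,
    core_index: int,
    allele: int,
    ehh_cutoff: float = 0.05,
) -> EhhCurve:
    """EHH decay curve for haplotypes carrying ``allele`` at ``core_index``.

    Requires at least 2 carriers of the core allele.
    """
    carriers = np.flatnonzero(matrix.alleles[:, core_index] == allele)
    if carriers.size < 2:
        raise ValueError(
            f"site {core_index}: fewer than 2 carriers of allele {allele}"
        )
    left, edge_l = _arm(
        matrix.alleles, matrix.positions, carriers, core_index, -1, ehh_cutoff
    )
    right, edge_r = _arm(
        matrix.alleles, matrix.positions, carriers, core_index, +1, ehh_cutoff
    )
    return EhhCurve(
        left=left, right=right, n_carriers=int(carriers.size),
        edge_left=edge_l, edge_right=edge_r,
    )


def ihh(curve: EhhCurve) -> float:
    """Integrated EHH: trapezoid rule against bp distance, both arms summed."""
    total = 0.0
    for arm in (curve.left, curve.right):
        if arm.shape[0] > 1:
            total += float(np.trapezoid(arm[:, 1], arm[:, 0]))
    return total


def _score(
    matrix: HaplotypeMatrix,
    core_index: int,
    metric: str,
    config: ScanConfig,
) -> SiteScore:
    daf = matrix.daf(core_index)
    pos = int(matrix.positions[core_index])
    invalid = SiteScore(core_index, pos, daf, math.nan, metric, False)
    maf = min(daf, 1.0 - daf)
    if not (maf > config.maf_floor):
        return invalid
    n1 = int(matrix.alleles[:, core_index].sum())
    n0 = matrix.n_hap - n1
    if n0 < 2 or n1 < 2:
        return invalid
    if metric == "ihs":
        stats = []
        for allele in (0, 1):
            curve = ehh_curve(matrix, core_index, allele, config.ehh_cutoff)
            if curve.reached_edge and config.truncation_policy == "skip":
                return invalid
            stats.append(ihh(curve))
    else:
        stats = [
            sl_statistic(matrix, core_index, allele) for allele in (0, 1)
        ]
    anc, der = stats
    if anc <= 0 or der <= 0:
        return invalid
    return SiteScore(core_index, pos, daf, math.log(anc / der), metric, True)


def ihs_unstandardized(
    matrix: HaplotypeMatrix, core_index: int, config: ScanConfig | None = None
) -> SiteScore:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) at one core site."""
    return _score(matrix, core_index, "ihs", config or ScanConfig())


def sl_statistic(matrix: HaplotypeMatrix, core_index: int, allele: int) -> float:
    """Mean shared-segment length (in sites, inclusive of the core) over pairs
    of haplotypes carrying ``allele`` at the core.

    Computed via the group-refinement identity
    ``mean L = 1 + sum_t EHH_left(t) + sum_t EHH_right(t)`` with no cutoff:
    the fraction of carrier pairs still identical t sites out equals EHH at
    that site.
    """
    carriers = np.flatnonzero(matrix.alleles[:, core_index] == allele)
    if carriers.size < 2:
        raise ValueError(
            f"site {core_index}: fewer than 2 carriers of allele {allele}"
        )
    npairs = _pairs(carriers.size)
    total_pair_sites = npairs  # every pair shares the core site itself
    for step in (-1, +1):
        profile = _arm_ehh_profile(
            matrix.alleles, carriers, core_index, step
        )  # integer pair counts; the sum runs to the chromosome edge
        total_pair_sites += int(profile.sum())
    return total_pair_sites / npairs


def nsl_unstandardized(
    matrix: HaplotypeMatrix, core_index: int, config: ScanConfig | None = None
) -> SiteScore:
    """Unstandardized nSL = ln(SL_ancestral / SL_derived) at one core site."""
    return _score(matrix, core_index, "nsl", config or ScanConfig())


def _merge_small_bins(
    assignments: np.ndarray, n_bins: int, min_count: int
) -> np.ndarray:
    """Merge under-populated bins into an adjacent bin until every remaining
    bin meets the floor or only one remains. The smallest offending bin is
    merged into whichever adjacent bin is smaller (ties toward lower DAF)."""
    # bins as ordered list of lists of original bin ids
    groups = [[b] for b in range(n_bins)]

    def counts() -> list[int]:
        return [
            int(np.isin(assignments, g).sum()) for g in groups
        ]

    while len(groups) > 1:
        c = counts()
        small = [i for i, n in enumerate(c) if n < min_count]
        if not small:
            break
        i = min(small, key=lambda i: (c[i], i))
        if i == 0:
            j = 1
        elif i == len(groups) - 1:
            j = i - 1
        else:
            j = i - 1 if c[i - 1] <= c[i + 1] else i + 1
        lo, hi = min(i, j), max(i, j)
        groups[lo] = groups[lo] + groups[hi]
        del groups[hi]
    remap = {}
    for new, g in enumerate(groups):
        for b in g:
            remap[b] = new
    return np.array([remap[b] for b in assignments], dtype=np.int64)


def standardize(
    scores: Sequence[SiteScore],
    n_daf_bins: int = 50,
    min_bin_count: int = 20,
) -> list[StandardizedScore]:
    """Standardize raw scores within derived-allele-frequency bins.

    Valid scores are binned into ``n_daf_bins`` equal-width DAF bins on (0, 1);
    bins holding fewer than ``min_bin_count`` scores are merged with an
    adjacent bin. Within each final bin, z = (raw - mean) / sd with the
    population (divide-by-n) standard deviation; a zero-sd bin yields z = 0.
    Invalid scores pass through with z = nan and bin_index = -1.
    """
    valid_idx = [i for i, s in enumerate(scores) if s.valid]
    if len(valid_idx) < 2:
        raise ValueError("need at least 2 valid scores to standardize")
    daf = np.array([scores[i].daf for i in valid_idx])
    raw = np.array([scores[i].raw for i in valid_idx])
    bins = np.clip((daf * n_daf_bins).astype(np.int64), 0, n_daf_bins - 1)
    bins = _merge_small_bins(bins, n_daf_bins, min_bin_count)
    z = np.empty_like(raw)
    for b in np.unique(bins):
        mask = bins == b
        mu = raw[mask].mean()
        sd = raw[mask].std()  # population sd
        z[mask] = 0.0 if sd == 0 else (raw[mask] - mu) / sd
    out: list[StandardizedScore] = []
    lookup = {orig: k for k, orig in enumerate(valid_idx)}
    for i, s in enumerate(scores):
        if i in lookup:
            k = lookup[i]
            out.append(
                StandardizedScore(
                    s.site_index, s.pos, s.daf, s.raw, s.metric, True,
                    z=float(z[k]), bin_index=int(bins[k]),
                )
            )
        else:
            out.append(
                StandardizedScore(
                    s.site_index, s.pos, s.daf, s.raw, s.metric, False
                )
            )
    return out
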