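"""Haplotype simulation for admixed-cohort imputation studies.

Two layers:

1. Differentiated source populations (``simulate_sources``): site frequencies
   follow a Balding-Nichols model around shared ancestral frequencies, and
   haplotypes are founder mosaics, which gives each population realistic
   linkage disequilibrium at a controllable effective haplotype diversity.
2. A single-pulse admixed cohort (``simulate_admixed``): each admixed
   haplotype is an ancestry mosaic with Poisson switch points at rate ``g``
   per Morgan (``g`` generations since the pulse), segment ancestries drawn
   from the admixture proportions, and each segment copied verbatim from one
   donor haplotype of that ancestry.  The generator returns the exact
   ancestry tracts alongside the haplotypes, so downstream stratification
   uses truth local ancestry rather than inferred calls.

Coordinates are 0-based, half-open throughout.  Any other generator that
returns the same ``(HaplotypeSet, AncestryTracks)`` pair (for example a
coalescent simulation) can be substituted upstream of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

ANCESTRIES = ("AFR", "EUR", "NAT")


@dataclass(frozen=True)
class ChromosomeSpec:
    """A chromosome with a monotone piecewise-linear genetic map.

    Parameters
    ----------
    length_bp:
        Physical length; positions live in ``[0, length_bp)``.
    rate_cM_per_Mb:
        Uniform recombination rate used when no map anchors are given.
    map_anchors_bp, map_anchors_cM:
        Optional anchors of a piecewise-linear bp -> cM map.  Must start at
        (0, 0), be non-decreasing in cM and strictly increasing in bp.
    """

    length_bp: int
    rate_cM_per_Mb: float = 1.0
    map_anchors_bp: np.ndarray | None = None
    map_anchors_cM: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if (self.map_anchors_bp is None) != (self.map_anchors_cM is None):
            raise ValueError("map anchors must be given for both bp and cM")
        if self.map_anchors_bp is not None:
            bp = np.asarray(self.map_anchors_bp, dtype=float)
            cm = np.asarray(self.map_anchors_cM, dtype=float)
            if bp.shape != cm.shape or bp.ndim != 1 or bp.size < 2:
                raise ValueError("map anchors must be 1-D arrays of equal length >= 2")
            if bp[0] != 0 or cm[0] != 0:
                raise ValueError("genetic map must anchor at (0, 0)")
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) < 0):
                raise ValueError("genetic map must be monotone")
            object.__setattr__(self, "map_anchors_bp", bp)
            object.__setattr__(self, "map_anchors_cM", cm)
        elif self.rate_cM_per_Mb < 0:
            raise ValueError("rate_cM_per_Mb must be non-negative")

    def bp_to_cM(self, pos_bp) -> np.ndarray:
        pos = np.asarray(pos_bp, dtype=float)
        if self.map_anchors_bp is None:
            return pos * self.rate_cM_per_Mb * 1e-6
        return np.interp(pos, self.map_anchors_bp, self.map_anchors_cM)

    def cM_to_bp(self, pos_cM) -> np.ndarray:
        pos = np.asarray(pos_cM, dtype=float)
        if self.map_anchors_bp is None:
            if self.rate_cM_per_Mb == 0:
                raise ValueError("cannot invert a flat genetic map")
            return pos / (self.rate_cM_per_Mb * 1e-6)
        return np.interp(pos, self.map_anchors_cM, self.map_anchors_bp)

    @property
    def length_cM(self) -> float:
        return float(self.bp_to_cM(self.length_bp))

    @property
    def length_morgans(self) -> float:
        return self.length_cM / 100.0


@dataclass(frozen=True)
class SourcePopConfig:
    """One differentiated source population.

    ``divergence_F`` is the Balding-Nichols differentiation coefficient
    (F_ST-like) from the shared ancestral frequencies; ``n_founders`` sets
    the effective haplotype diversity; ``founder_switch_rate`` (switches per
    Morgan) sets the scale of ancestral LD; ``mutation_flip_rate`` adds
    per-site, per-haplotype allele flips (private-mutation noise).
    """

    label: str
    n_haplotypes: int
    n_founders: int
    divergence_F: float
    founder_switch_rate: float
    mutation_flip_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ANCESTRIES:
            raise ValueError(f"label must be one of {ANCESTRIES}, got {self.label!r}")
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.n_haplotypes < 2 or self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be an even number >= 2")
        if not (0.0 < self.divergence_F < 1.0):
            raise ValueError("divergence_F must lie in (0, 1)")
        if self.founder_switch_rate < 0 or self.mutation_flip_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class AdmixtureConfig:
    """Single-pulse three-way admixture: proportions (AFR, EUR, NAT), the
    number of generations since the pulse, and the cohort size."""

    proportions: tuple[float, float, float]
    generations_ago: int
    n_individuals: int

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or np.any(p > 1):
            raise ValueError("proportions must be three values in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if self.generations_ago < 1:
            raise ValueError("generations_ago must be >= 1")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes with physical and genetic coordinates.

    ``alleles`` is an (H, L) uint8 matrix in {0, 1}; haplotypes ``2i`` and
    ``2i + 1`` form individual ``i``.  ``sample_ids`` repeats each
    individual's identifier on both of its haplotypes; ``populations``
    carries a population label per haplotype.
    """

    alleles: np.ndarray
    positions_bp: np.ndarray
    positions_cM: np.ndarray
    sample_ids: np.ndarray
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.positions_cM = np.asarray(self.positions_cM, dtype=np.float64)
        self.sample_ids = np.asarray(self.sample_ids)
        self.populations = np.asarray(self.populations)

    def validate(self) -> None:
        H, L = self.alleles.shape
        if self.positions_bp.shape != (L,) or self.positions_cM.shape != (L,):
            raise ValueError("positions do not match allele matrix width")
        if self.sample_ids.shape != (H,) or self.populations.shape != (H,):
            raise ValueError("labels do not match haplotype count")
        if L and (np.any(np.diff(self.positions_bp) <= 0)):
            raise ValueError("positions_bp must be strictly increasing")
        if L and np.any(np.diff(self.positions_cM) < 0):
            raise ValueError("positions_cM must be non-decreasing")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("alleles must be binary")
        if H % 2:
            raise ValueError("haplotype count must be even (diploid pairing)")
        if not np.all(self.sample_ids[0::2] == self.sample_ids[1::2]):
            raise ValueError("haplotype pairs (2i, 2i+1) must share a sample id")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.n_haplotypes // 2

    def individual_ids(self) -> np.ndarray:
        return self.sample_ids[0::2]

    def haplotype_labels(self) -> np.ndarray:
        suffix = np.where(np.arange(self.n_haplotypes) % 2 == 0, "_1", "_2")
        return np.char.add(self.sample_ids.astype(str), suffix)

    def take_sites(self, idx) -> "HaplotypeSet":
        idx = np.asarray(idx, dtype=np.intp)
        return HaplotypeSet(
            self.alleles[:, idx],
            self.positions_bp[idx],
            self.positions_cM[idx],
            self.sample_ids.copy(),
            self.populations.copy(),
        )

    def take_haplotypes(self, idx) -> "HaplotypeSet":
        idx = np.asarray(idx, dtype=np.intp)
        return HaplotypeSet(
            self.alleles[idx],
            self.positions_bp.copy(),
            self.positions_cM.copy(),
            self.sample_ids[idx],
            self.populations[idx],
        )

    def take_individuals(self, ind_idx) -> "HaplotypeSet":
        ind_idx = np.asarray(ind_idx, dtype=np.intp)
        hap_idx = np.empty(2 * ind_idx.size, dtype=np.intp)
        hap_idx[0::2] = 2 * ind_idx
        hap_idx[1::2] = 2 * ind_idx + 1
        return self.take_haplotypes(hap_idx)

    def pop_mask(self, pop: str) -> np.ndarray:
        return self.populations == pop

    @staticmethod
    def concat_haplotypes(sets: Sequence["HaplotypeSet"]) -> "HaplotypeSet":
        first = sets[0]
        for other in sets[1:]:
            if not np.array_equal(first.positions_bp, other.positions_bp):
                raise ValueError("cannot concatenate haplotype sets with different sites")
        return HaplotypeSet(
            np.vstack([s.alleles for s in sets]),
            first.positions_bp.copy(),
            first.positions_cM.copy(),
            np.concatenate([s.sample_ids for s in sets]),
            np.concatenate([s.populations for s in sets]),
        )


@dataclass
class AncestryTracks:
    """Per-haplotype ordered partition of ``[0, length_bp)`` into
    ancestry-labeled half-open intervals, aligned with a HaplotypeSet's
    haplotype order."""

    length_bp: int
    starts: list  # per haplotype: int64 array of tract starts
    ends: list  # per haplotype: int64 array of tract ends
    labels: list  # per haplotype: array of ancestry labels
    sample_ids: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return len(self.starts)

    def validate(self) -> None:
        for s, e, lab in zip(self.starts, self.ends, self.labels):
            if len(s) == 0:
                raise ValueError("haplotype with no tracts")
            if s[0] != 0 or e[-1] != self.length_bp:
                raise ValueError("tracts must span [0, length_bp)")
            if np.any(e <= s) or np.any(s[1:] != e[:-1]):
                raise ValueError("tracts must tile the chromosome without gaps or overlaps")
            if np.any(lab[1:] == lab[:-1]):
                raise ValueError("adjacent tracts must differ in ancestry (normalize first)")

    def ancestry_at(self, hap_index: int, pos_bp: int) -> str:
        if not (0 <= pos_bp < self.length_bp):
            raise ValueError(f"position {pos_bp} outside chromosome")
        k = int(np.searchsorted(self.starts[hap_index], pos_bp, side="right")) - 1
        return str(self.labels[hap_index][k])

    def ancestry_vector(self, hap_index: int, pos_bp: np.ndarray) -> np.ndarray:
        """Ancestry label for each query position on one haplotype."""
        pos = np.asarray(pos_bp)
        if pos.size and (pos.min() < 0 or pos.max() >= self.length_bp):
            raise ValueError("position outside chromosome")
        k = np.searchsorted(self.starts[hap_index], pos, side="right") - 1
        return np.asarray(self.labels[hap_index])[k]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        hap_labels = _hap_labels(self.sample_ids)
        for h in range(self.n_haplotypes):
            for s, e, lab in zip(self.starts[h], self.ends[h], self.labels[h]):
                rows.append((hap_labels[h], int(s), int(e), str(lab)))
        return pd.DataFrame(rows, columns=["haplotype_id", "start_bp", "end_bp", "ancestry"])


def _hap_labels(sample_ids: np.ndarray) -> np.ndarray:
    suffix = np.where(np.arange(len(sample_ids)) % 2 == 0, "_1", "_2")
    return np.char.add(np.asarray(sample_ids).astype(str), suffix)


def _merge_adjacent(starts, ends, labels):
    """Merge runs of equal adjacent labels into single tracts."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    labels = np.asarray(labels)
    keep = np.ones(len(labels), dtype=bool)
    keep[1:] = labels[1:] != labels[:-1]
    out_starts = starts[keep]
    out_labels = labels[keep]
    out_ends = np.empty_like(out_starts)
    out_ends[:-1] = out_starts[1:]
    out_ends[-1] = ends[-1]
    return out_starts, out_ends, out_labels


def _founder_paths(chrom: ChromosomeSpec, n_haps: int, n_founders: int,
                   switch_rate: float, rng: np.random.Generator):
    """Founder-mosaic path per haplotype: (breaks_bp, founder index per segment)."""
    total_m = chrom.length_morgans
    paths = []
    for _ in range(n_haps):
        n_sw = rng.poisson(switch_rate * total_m) if switch_rate > 0 else 0
        if n_sw:
            cm = np.sort(rng.uniform(0.0, chrom.length_cM, n_sw))
            bp = np.unique(np.clip(chrom.cM_to_bp(cm).astype(np.int64), 1, chrom.length_bp - 1))
        else:
            bp = np.empty(0, dtype=np.int64)
        breaks = np.concatenate(([0], bp))
        founders = rng.integers(0, n_founders, size=len(breaks))
        paths.append((breaks, founders))
    return paths


def simulate_sources(chrom: ChromosomeSpec, pops: Sequence[SourcePopConfig],
                     n_sites: int, seed: int) -> HaplotypeSet:
    """Simulate phased haplotypes for differentiated source populations.

    Per site, an ancestral frequency q ~ U(0.02, 0.98) is drawn; each
    population's frequency comes from Balding-Nichols(q, F); founders sample
    alleles Bernoulli(p); sample haplotypes read alleles off their founder
    mosaic and flip each site independently at the mutation flip rate.
    Sites monomorphic across all populations combined are dropped and
    redrawn so the output contains exactly ``n_sites`` segregating sites
    (at most ``10 * n_sites`` candidate draws).
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    labels = [p.label for p in pops]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicated population label")
    rng = np.random.default_rng(seed)

    paths = {p.label: _founder_paths(chrom, p.n_haplotypes, p.n_founders,
                                     p.founder_switch_rate, rng)
             for p in pops}

    kept_pos: list[np.ndarray] = []
    kept_cols: list[np.ndarray] = []
    used_positions: set[int] = set()
    n_kept = 0
    draws = 0
    cap = 10 * n_sites
    H_total = sum(p.n_haplotypes for p in pops)

    while n_kept < n_sites:
        m = min(n_sites - n_kept + 16, cap - draws)
        if m <= 0:
            raise RuntimeError(
                f"could not obtain {n_sites} segregating sites within {cap} draws")
        draws += m
        pos = rng.integers(0, chrom.length_bp, size=m)
        q = rng.uniform(0.02, 0.98, size=m)
        cols = np.empty((H_total, m), dtype=np.uint8)
        row = 0
        for p in pops:
            a = q * (1.0 - p.divergence_F) / p.divergence_F
            b = (1.0 - q) * (1.0 - p.divergence_F) / p.divergence_F
            freqs = rng.beta(a, b)
            founder_alleles = (rng.random((p.n_founders, m)) < freqs).astype(np.uint8)
            for breaks, founders in paths[p.label]:
                seg = np.searchsorted(breaks, pos, side="right") - 1
                hap = founder_alleles[founders[seg], np.arange(m)]
                if p.mutation_flip_rate > 0:
                    hap = hap ^ (rng.random(m) < p.mutation_flip_rate)
                cols[row] = hap
                row += 1
        counts = cols.sum(axis=0)
        fresh = np.fromiter((int(x) not in used_positions for x in pos),
                            dtype=bool, count=m)
        # intra-batch duplicates: keep first occurrence only
        _, first_idx = np.unique(pos, return_index=True)
        first = np.zeros(m, dtype=bool)
        first[first_idx] = True
        ok = (counts > 0) & (counts < H_total) & fresh & first
        if ok.any():
            kept_pos.append(pos[ok])
            kept_cols.append(cols[:, ok])
            used_positions.update(int(x) for x in pos[ok])
            n_kept += int(ok.sum())

    # trim overshoot in draw order (independent of position) before sorting
    positions = np.concatenate(kept_pos)[:n_sites]
    alleles = np.concatenate(kept_cols, axis=1)[:, :n_sites]
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    alleles = np.ascontiguousarray(alleles[:, order])

    sample_ids = np.concatenate([
        np.repeat([f"{p.label}{i:04d}" for i in range(p.n_haplotypes // 2)], 2)
        for p in pops
    ])
    populations = np.concatenate([np.repeat(p.label, p.n_haplotypes) for p in pops])
    out = HaplotypeSet(alleles, positions, chrom.bp_to_cM(positions),
                       sample_ids, populations)
    return out


def simulate_admixed(sources: HaplotypeSet, cfg: AdmixtureConfig,
                     chrom: ChromosomeSpec, seed: int,
                     sample_prefix: str = "ADM") -> tuple[HaplotypeSet, AncestryTracks]:
    """Build a single-pulse admixed cohort as ancestry mosaics of source
    haplotypes, returning the cohort and its exact truth tracts.

    Ancestry-switch points are Poisson with rate ``generations_ago`` per
    Morgan along the genetic map; each segment's ancestry is an independent
    draw from the admixture proportions (a switch may redraw the same
    ancestry), and its sequence is copied from one uniformly chosen donor
    haplotype of that ancestry.
    """
    rng = np.random.default_rng(seed)
    props = np.asarray(cfg.proportions, dtype=float)
    props = props / props.sum()
    donor_idx = {}
    for k, anc in enumerate(ANCESTRIES):
        idx = np.flatnonzero(sources.pop_mask(anc))
        if props[k] > 0 and idx.size < 2:
            raise ValueError(f"ancestry {anc} has proportion > 0 but fewer than 2 "
                             "source haplotypes")
        donor_idx[anc] = idx

    n_hap = 2 * cfg.n_individuals
    g = cfg.generations_ago
    pos = sources.positions_bp
    L = sources.n_sites
    alleles = np.empty((n_hap, L), dtype=np.uint8)
    all_starts, all_ends, all_labels = [], [], []

    for h in range(n_hap):
        n_sw = rng.poisson(g * chrom.length_morgans)
        if n_sw:
            cm = np.sort(rng.uniform(0.0, chrom.length_cM, n_sw))
            bp = np.unique(np.clip(chrom.cM_to_bp(cm).astype(np.int64), 1,
                                   chrom.length_bp - 1))
        else:
            bp = np.empty(0, dtype=np.int64)
        seg_starts = np.concatenate(([0], bp))
        seg_ends = np.concatenate((bp, [chrom.length_bp]))
        anc_codes = rng.choice(3, size=len(seg_starts), p=props)
        seg_labels = np.asarray(ANCESTRIES)[anc_codes]
        lo = np.searchsorted(pos, seg_starts, side="left")
        hi = np.searchsorted(pos, seg_ends, side="left")
        for s, e, anc in zip(lo, hi, seg_labels):
            donors = donor_idx[str(anc)]
            donor = donors[rng.integers(0, donors.size)]
            if e > s:
                alleles[h, s:e] = sources.alleles[donor, s:e]
        st, en, lab = _merge_adjacent(seg_starts, seg_ends, seg_labels)
        all_starts.append(st)
        all_ends.append(en)
        all_labels.append(lab)

    sample_ids = np.repeat([f"{sample_prefix}{i:04d}" for i in range(cfg.n_individuals)], 2)
    populations = np.repeat("ADM", n_hap)
    haps = HaplotypeSet(alleles, pos.copy(), sources.positions_cM.copy(),
                        sample_ids, populations)
    tracks = AncestryTracks(chrom.length_bp, all_starts, all_ends, all_labels,
                            sample_ids.copy())
    return haps, tracks


def ancestry_fractions(tracks: AncestryTracks, per: str = "individual") -> pd.DataFrame:
    """Genome fraction of each ancestry from truth tracts.

    Per haplotype, the fraction is the summed tract length per ancestry over
    the chromosome length; per individual it is the mean of the two
    haplotypes.  Rows sum to 1.
    """
    if per not in ("individual", "haplotype"):
        raise ValueError("per must be 'individual' or 'haplotype'")
    frac = np.zeros((tracks.n_haplotypes, len(ANCESTRIES)))
    for h in range(tracks.n_haplotypes):
        lengths = (tracks.ends[h] - tracks.starts[h]).astype(float)
        labs = np.asarray(tracks.labels[h])
        for k, anc in enumerate(ANCESTRIES):
            frac[h, k] = lengths[labs == anc].sum() / tracks.length_bp
    if per == "haplotype":
        return pd.DataFrame(frac, index=_hap_labels(tracks.sample_ids),
                            columns=list(ANCESTRIES))
    ind = (frac[0::2] + frac[1::2]) / 2.0
    return pd.DataFrame(ind, index=np.asarray(tracks.sample_ids)[0::2],
                        columns=list(ANCESTRIES))
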