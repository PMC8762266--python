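"""Stratified imputation accuracy and the incremental-reference-panel
experiment.

Accuracy is the squared Pearson correlation between imputed and true
alternate-allele dosages, pooled over (individual, site) observations
within each local-ancestry-diplotype x frequency-class stratum (a
per-individual-then-average mode is also available).  The incremental
experiment imputes a fixed target cohort against a base reference panel
plus nested, growing subsets of reference individuals from the
underrepresented ancestry, and the gap analysis reports the smallest
addition at which accuracy in double-NAT ancestry tracts reaches that in
double-EUR tracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import arraydesign, hmm
from .sim import (ANCESTRIES, AdmixtureConfig, AncestryTracks, ChromosomeSpec,
                  HaplotypeSet, SourcePopConfig, ancestry_fractions,
                  simulate_admixed, simulate_sources)
from .strata import FreqBins, diplotype_matrix

NAT_CONTAINING = ("AFR_NAT", "EUR_NAT", "NAT_NAT")


@dataclass(frozen=True)
class QualityThreshold:
    """GWAS quality filter: MAF >= min_maf and INFO > min_info."""

    min_maf: float = 0.01
    min_info: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must lie in [0, 0.5]")
        if not (0.0 <= self.min_info <= 1.0):
            raise ValueError("min_info must lie in [0, 1]")


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; NaN when undefined (fewer than 2 points,
    zero variance in either vector, or < 2 distinct truth values)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.unique(y).size < 2:
        return float("nan")
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    c = np.cov(x, y, ddof=0)
    return float(c[0, 1] ** 2 / (c[0, 0] * c[1, 1]))


def dosage_r2(imputed: np.ndarray, true: np.ndarray, diplotypes: np.ndarray,
              bins_of_site: np.ndarray, mode: str = "pooled") -> pd.DataFrame:
    """Stratified dosage r-squared.

    ``imputed`` and ``true`` are (N, L) dosage matrices aligned on
    (individual, site); ``diplotypes`` is the (N, L) diplotype label matrix
    and ``bins_of_site`` the (L,) frequency-class labels (EXCLUDED sites are
    dropped).  ``mode="pooled"`` pools observations within a stratum;
    ``mode="per_individual"`` averages per-individual r-squared values.
    Undefined strata carry NaN, never 0.
    """
    imputed = np.asarray(imputed, dtype=float)
    true = np.asarray(true, dtype=float)
    if imputed.shape != true.shape or imputed.shape != diplotypes.shape:
        raise ValueError("imputed, true and diplotype matrices must be aligned")
    if mode not in ("pooled", "per_individual"):
        raise ValueError("mode must be 'pooled' or 'per_individual'")
    N, L = imputed.shape
    df = pd.DataFrame({
        "ind": np.repeat(np.arange(N), L),
        "diplotype": np.asarray(diplotypes, dtype=object).ravel(),
        "bin": np.tile(np.asarray(bins_of_site, dtype=object), N),
        "imp": imputed.ravel(),
        "true": true.ravel(),
    })
    df = df[df["bin"] != "EXCLUDED"]
    rows = []
    for (dip, b), grp in df.groupby(["diplotype", "bin"], sort=True):
        if mode == "pooled":
            r2 = _pearson_r2(grp["imp"].to_numpy(), grp["true"].to_numpy())
        else:
            vals = [_pearson_r2(g["imp"].to_numpy(), g["true"].to_numpy())
                    for _, g in grp.groupby("ind")]
            vals = [v for v in vals if not np.isnan(v)]
            r2 = float(np.mean(vals)) if vals else float("nan")
        rows.append({"diplotype": dip, "maf_bin": b,
                     "n_observations": len(grp), "r2": r2})
    return pd.DataFrame(rows)


def count_above_threshold(maf: np.ndarray, info: np.ndarray,
                          thr: QualityThreshold = QualityThreshold(),
                          stratum: np.ndarray | None = None):
    """Number of sites passing the quality filter (MAF inclusive, INFO
    strict), overall or per stratum label."""
    maf = np.asarray(maf, dtype=float)
    info = np.asarray(info, dtype=float)
    passing = (maf >= thr.min_maf) & (info > thr.min_info)
    if stratum is None:
        return int(passing.sum())
    return pd.Series(passing).groupby(np.asarray(stratum)).sum().astype(int)


def per_individual_info(probs: np.ndarray) -> np.ndarray:
    """INFO computed per individual (N = 1 convention) at every site;
    probs has shape (N, L, 3), the result (N, L)."""
    p = np.asarray(probs, dtype=float)
    e = p[..., 1] + 2.0 * p[..., 2]
    f = p[..., 1] + 4.0 * p[..., 2]
    theta = e / 2.0
    denom = 2.0 * theta * (1.0 - theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        info = np.where(denom > 0, 1.0 - (f - e * e) / np.where(denom > 0, denom, 1.0), 1.0)
    return np.clip(info, 0.0, 1.0)


def per_individual_counts(probs: np.ndarray, maf: np.ndarray,
                          thr: QualityThreshold = QualityThreshold()) -> np.ndarray:
    """Per-individual count of sites passing the quality filter, with INFO
    from that individual's own genotype probabilities (N = 1)."""
    info = per_individual_info(probs)
    maf = np.asarray(maf, dtype=float)
    passing = (maf[None, :] >= thr.min_maf) & (info > thr.min_info)
    return passing.sum(axis=1)


def compare_panels_paired(counts_a: np.ndarray, counts_b: np.ndarray) -> dict:
    """Two-tailed paired t-test on per-individual counts under two panels.

    Returns mean difference (B - A), t, df and p; with zero-variance
    differences the test is undefined and flagged.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need matched count vectors for >= 2 individuals")
    diff = b - a
    out = {"mean_diff": float(diff.mean()), "df": int(a.size - 1)}
    if diff.std(ddof=1) == 0:
        out.update({"t": float("nan"), "p": float("nan"), "undefined": True})
        return out
    res = stats.ttest_rel(b, a)
    out.update({"t": float(res.statistic), "p": float(res.pvalue), "undefined": False})
    return out


def composition_table(counts: dict[str, int]) -> pd.DataFrame:
    """Panel composition summary: per-source genome counts and their
    percentage of the panel, truncated to one decimal (103/134 prints as
    76.8, not 76.9)."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("panel must contain at least one genome")
    return pd.DataFrame({
        "source": list(counts),
        "n_genomes": list(counts.values()),
        "percent": [np.floor(1000.0 * v / total) / 10 for v in counts.values()],
    })


# ---------------------------------------------------------------------------
# Incremental-reference-panel experiment
# ---------------------------------------------------------------------------

#: Base-panel composition ratios mirroring a 1KGP-like reference
#: (AFR : EUR : admixed individuals).
BASE_PANEL_RATIOS = (661, 503, 347)
N_TARGETS_FULL = 300


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for one incremental-panel experiment.

    The default constructor carries the desk-scale (0.1x) configuration;
    ``ExperimentConfig.at_scale`` derives panel counts from the full-scale
    ratios (base panel AFR:EUR:admixed = 661:503:347 individuals, 300
    targets) times a scale factor.
    """

    length_bp: int = 50_000_000
    rate_cM_per_Mb: float = 1.0
    n_sites: int = 8_000
    n_afr_panel: int = 66
    n_eur_panel: int = 50
    n_adm_panel: int = 35
    n_targets: int = 30
    added_sizes: tuple = (0, 20, 50, 100)
    donor_haps_per_ancestry: int = 80
    n_founders: int = 40
    founder_switch_rate: float = 30.0
    mutation_flip_rate: float = 5e-4
    divergence_F: tuple = (0.08, 0.06, 0.12)  # AFR, EUR, NAT
    proportions: tuple = (1 / 6, 1 / 3, 1 / 2)
    generations_ago: int = 12
    ascertainment_pop: str = "EUR"
    target_spacing_bp: float = 25_000.0
    maf_bin_edges: tuple = arraydesign.DEFAULT_MAF_BIN_EDGES
    maf_bin_proportions: tuple = arraydesign.DEFAULT_MAF_BIN_PROPORTIONS
    nat_pool_size: int = 0  # floor on the simulated NAT reference pool
    ls: hmm.LSParams = field(default_factory=hmm.LSParams)

    def __post_init__(self) -> None:
        if tuple(sorted(self.added_sizes)) != tuple(self.added_sizes):
            raise ValueError("added_sizes must be sorted ascending")

    @property
    def chromosome(self) -> ChromosomeSpec:
        return ChromosomeSpec(self.length_bp, self.rate_cM_per_Mb)

    @property
    def nat_pool(self) -> int:
        return max(max(self.added_sizes), self.nat_pool_size)

    @classmethod
    def at_scale(cls, scale: float = 0.1, added_sizes: tuple = (0, 20, 50, 100),
                 **overrides) -> "ExperimentConfig":
        r = BASE_PANEL_RATIOS
        return cls(
            n_afr_panel=round(r[0] * scale),
            n_eur_panel=round(r[1] * scale),
            n_adm_panel=round(r[2] * scale),
            n_targets=round(N_TARGETS_FULL * scale),
            added_sizes=tuple(added_sizes),
            **overrides,
        )

    def source_pops(self) -> list[SourcePopConfig]:
        panel_ind = {"AFR": self.n_afr_panel, "EUR": self.n_eur_panel,
                     "NAT": self.nat_pool}
        return [
            SourcePopConfig(anc, 2 * panel_ind[anc] + self.donor_haps_per_ancestry,
                            self.n_founders, self.divergence_F[k],
                            self.founder_switch_rate, self.mutation_flip_rate)
            for k, anc in enumerate(ANCESTRIES)
        ]


@dataclass
class StudyData:
    """One simulated study: sources split into panel/donor roles, the
    admixed cohort with truth tracts, and the ascertained array."""

    chrom: ChromosomeSpec
    sources: HaplotypeSet
    panel_members: dict  # ancestry -> haplotype indices reserved for panels
    donor_members: dict  # ancestry -> haplotype indices used as admixture donors
    cohort: HaplotypeSet  # panel admixed + targets, in that order
    tracks: AncestryTracks
    scheme: arraydesign.ArrayScheme
    n_adm_panel: int
    seeds: dict


def derive_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-stage seeds from one master seed (stage i uses the
    i-th word of the master SeedSequence state, folded below 2**31)."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2 ** 31)) for s in state]


def simulate_study(cfg: ExperimentConfig, seed: int) -> StudyData:
    """Simulate sources, the admixed cohort and the array for one seed."""
    s_src, s_adm, s_arr, _ = derive_seeds(seed)
    chrom = cfg.chromosome
    sources = simulate_sources(chrom, cfg.source_pops(), cfg.n_sites, s_src)

    panel_members, donor_members = {}, {}
    panel_ind = {"AFR": cfg.n_afr_panel, "EUR": cfg.n_eur_panel, "NAT": cfg.nat_pool}
    for anc in ANCESTRIES:
        idx = np.flatnonzero(sources.pop_mask(anc))
        panel_members[anc] = idx[: 2 * panel_ind[anc]]
        donor_members[anc] = idx[2 * panel_ind[anc]:]

    donors = sources.take_haplotypes(
        np.concatenate([donor_members[a] for a in ANCESTRIES]))
    adm_cfg = AdmixtureConfig(cfg.proportions, cfg.generations_ago,
                              cfg.n_adm_panel + cfg.n_targets)
    cohort, tracks = simulate_admixed(donors, adm_cfg, chrom, s_adm)

    scheme = arraydesign.ascertain_sites(
        sources, chrom, cfg.ascertainment_pop, cfg.target_spacing_bp,
        cfg.maf_bin_edges, cfg.maf_bin_proportions, s_arr)
    return StudyData(chrom, sources, panel_members, donor_members, cohort,
                     tracks, scheme, cfg.n_adm_panel,
                     {"sources": s_src, "admixed": s_adm, "array": s_arr})


def build_panel(study: StudyData, added_nat: int) -> HaplotypeSet:
    """Base reference panel (AFR + EUR + admixed panel individuals) plus the
    first ``added_nat`` NAT reference individuals (nested subsets)."""
    nat_idx = study.panel_members["NAT"][: 2 * added_nat]
    if nat_idx.size < 2 * added_nat:
        raise ValueError(f"NAT pool holds only {nat_idx.size // 2} individuals; "
                         f"cannot add {added_nat}")
    parts = [study.sources.take_haplotypes(study.panel_members["AFR"]),
             study.sources.take_haplotypes(study.panel_members["EUR"]),
             study.cohort.take_individuals(np.arange(study.n_adm_panel))]
    if added_nat:
        parts.append(study.sources.take_haplotypes(nat_idx))
    return HaplotypeSet.concat_haplotypes(parts)


@dataclass
class ExperimentResult:
    """Raw per-size imputation output at held-out sites, ready for
    stratified accuracy tables under any frequency binning."""

    sizes: tuple
    heldout_positions: np.ndarray
    truth_maf: np.ndarray  # cohort truth MAF at held-out sites
    true_dosages: np.ndarray  # (N_targets, L_heldout)
    diplotypes: np.ndarray  # (N_targets, L_heldout)
    dosages: dict  # size -> (N_targets, L_heldout)
    info: dict  # size -> (L_heldout,) pooled over targets
    probs: dict  # size -> (N_targets, L_heldout, 3)
    sample_ids: np.ndarray
    seeds: dict
    minor_is_ref: np.ndarray | None = None  # sites where allele 1 is the major allele

    def fold_to_minor(self, dose: np.ndarray) -> np.ndarray:
        """Orient a dosage matrix to the cohort minor allele (d -> 2 - d at
        sites where the alternate allele is the major one).  Pooled
        correlations on folded dosages measure minor-allele recovery rather
        than between-site mean structure."""
        if self.minor_is_ref is None:
            return dose
        out = dose.copy()
        out[:, self.minor_is_ref] = 2.0 - out[:, self.minor_is_ref]
        return out


def run_incremental_experiment(cfg: ExperimentConfig, seed: int,
                               study: StudyData | None = None) -> ExperimentResult:
    """Impute the target cohort against the base panel plus each added-NAT
    panel size and collect dosages, genotype probabilities and INFO at the
    held-out sites."""
    if study is None:
        study = simulate_study(cfg, seed)
    typed_idx = study.scheme.typed_site_indices
    heldout_idx = np.setdiff1d(np.arange(study.sources.n_sites), typed_idx)

    targets = study.cohort.take_individuals(
        np.arange(study.n_adm_panel, study.cohort.n_individuals))
    target_hap_offset = 2 * study.n_adm_panel
    target_tracks_idx = np.arange(target_hap_offset, study.cohort.n_haplotypes)

    truth_freq = study.cohort.alleles.mean(axis=0)[heldout_idx]
    truth_maf = np.minimum(truth_freq, 1.0 - truth_freq)
    true_dose = (targets.alleles[0::2] + targets.alleles[1::2]).astype(float)[:, heldout_idx]

    sub_tracks = AncestryTracks(
        study.tracks.length_bp,
        [study.tracks.starts[h] for h in target_tracks_idx],
        [study.tracks.ends[h] for h in target_tracks_idx],
        [study.tracks.labels[h] for h in target_tracks_idx],
        np.asarray(study.tracks.sample_ids)[target_tracks_idx])
    dips = diplotype_matrix(sub_tracks, study.sources.positions_bp[heldout_idx])

    dosages, infos, probs_all = {}, {}, {}
    for s in cfg.added_sizes:
        panel = build_panel(study, s)
        hap_probs = hmm.impute_haplotypes(targets.alleles[:, typed_idx],
                                          panel, typed_idx, cfg.ls)
        gp = hmm.haploid_to_genotype(hap_probs[0::2], hap_probs[1::2])[:, heldout_idx]
        dosages[s] = hmm.dosage(gp)
        infos[s] = hmm.info_scores(gp)
        probs_all[s] = gp
    return ExperimentResult(tuple(cfg.added_sizes),
                            study.sources.positions_bp[heldout_idx], truth_maf,
                            true_dose, dips, dosages, infos, probs_all,
                            targets.individual_ids(), study.seeds,
                            minor_is_ref=truth_freq > 0.5)


def accuracy_table(result: ExperimentResult, bins: FreqBins = FreqBins(),
                   thr: QualityThreshold = QualityThreshold(),
                   mode: str = "pooled") -> pd.DataFrame:
    """Long-format accuracy table: one row per added-panel size x diplotype
    x frequency class, with r2 on minor-allele-oriented dosages, mean INFO,
    and the mean per-individual count of sites passing the quality filter."""
    bin_names = bins.assign(result.truth_maf)
    true_folded = result.fold_to_minor(result.true_dosages)
    frames = []
    for s in result.sizes:
        tab = dosage_r2(result.fold_to_minor(result.dosages[s]), true_folded,
                        result.diplotypes, bin_names, mode=mode)
        info = result.info[s]
        pind_info = per_individual_info(result.probs[s])
        mean_info, snps = [], []
        for _, row in tab.iterrows():
            in_bin = bin_names == row["maf_bin"]
            dip_mask = result.diplotypes == row["diplotype"]
            cell = dip_mask & in_bin[None, :]
            mean_info.append(float(info[in_bin].mean()) if in_bin.any() else float("nan"))
            passing = ((result.truth_maf[None, :] >= thr.min_maf)
                       & (pind_info > thr.min_info) & cell)
            snps.append(float(passing.sum(axis=1).mean()))
        tab["mean_info"] = mean_info
        tab["snps_above_threshold"] = snps
        tab.insert(0, "added_refs", s)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def gap_analysis(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per frequency class: the smallest added-reference size at which
    NAT_NAT r2 reaches EUR_EUR r2, and the improvement-over-baseline curve
    delta-r2(s) = r2(s) - r2(0) for the NAT_NAT stratum.

    Returns ``(gaps, deltas)``; a class where the gap never closes carries
    ``reached = False`` and a missing size; strata absent from the table
    are flagged missing rather than fabricated.
    """
    required = {"added_refs", "diplotype", "maf_bin", "r2"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must contain columns {sorted(required)}")
    gap_rows, delta_rows = [], []
    for b, sub in table.groupby("maf_bin", sort=True):
        nat = sub[sub["diplotype"] == "NAT_NAT"].set_index("added_refs")["r2"]
        eur = sub[sub["diplotype"] == "EUR_EUR"].set_index("added_refs")["r2"]
        sizes = sorted(set(nat.index) & set(eur.index))
        if not sizes:
            gap_rows.append({"maf_bin": b, "gap_closing_size": float("nan"),
                             "reached": False, "missing_strata": True})
            continue
        closing = next((s for s in sizes
                        if not np.isnan(nat[s]) and not np.isnan(eur[s])
                        and nat[s] >= eur[s]), None)
        gap_rows.append({
            "maf_bin": b,
            "gap_closing_size": float("nan") if closing is None else closing,
            "reached": closing is not None,
            "missing_strata": False,
        })
        base = nat.get(min(sizes), float("nan"))
        for s in sizes:
            delta_rows.append({"maf_bin": b, "added_refs": s,
                               "delta_r2": float(nat[s] - base)})
    return pd.DataFrame(gap_rows), pd.DataFrame(delta_rows)
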