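"""Reference-based genotype imputation with a haploid copying HMM.

Each target haplotype is modeled as an imperfect mosaic of the ``H``
reference haplotypes (the Li-Stephens model): the hidden state at typed
site ``j`` is the reference haplotype being copied, switches between
adjacent typed sites occur with probability

    s_j = max(min_switch, 1 - exp(-4 * Ne_eff * d_j / H))

where ``d_j`` is the genetic distance in Morgans, and the observed allele
differs from the copied allele with the mis-copy probability ``lambda``.
Posterior copying probabilities come from the scaled forward-backward
recursions; at untyped sites the posterior is linearly interpolated in
genetic distance between the flanking typed sites.  Haploid allele
probabilities for the two haplotypes of an individual are combined
multiplicatively into genotype probabilities (P(AA), P(Aa), P(aa)), from
which dosages and IMPUTE-style INFO scores follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sim import HaplotypeSet

#: A reference panel is simply a phased HaplotypeSet with >= 2 haplotypes.
ReferencePanel = HaplotypeSet

MISSING = -1


@dataclass(frozen=True)
class LSParams:
    """Copying-model parameters.

    ne_eff : effective population size in the switch-rate map (default 1e4).
    miscopy_lambda : P(observed allele != copied allele), in (0, 0.5).
    min_switch : floor on the per-interval switch probability.
    """

    ne_eff: float = 1.0e4
    miscopy_lambda: float = 1.0e-3
    min_switch: float = 1.0e-8

    def __post_init__(self) -> None:
        if self.ne_eff <= 0:
            raise ValueError("ne_eff must be positive")
        if not (0.0 < self.miscopy_lambda < 0.5):
            raise ValueError("miscopy_lambda must lie in (0, 0.5)")
        if self.min_switch < 0 or self.min_switch >= 1:
            raise ValueError("min_switch must lie in [0, 1)")


@dataclass
class GenotypeProbs:
    """Per-individual, per-site genotype probability triplets.

    ``probs`` has shape (N, L, 3) ordered (P(AA), P(Aa), P(aa)) with AA the
    homozygous-reference genotype; each triplet sums to 1.
    """

    probs: np.ndarray
    sample_ids: np.ndarray
    positions_bp: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 3 or self.probs.shape[2] != 3:
            raise ValueError("probs must have shape (N, L, 3)")

    def validate(self) -> None:
        if np.any(self.probs < -1e-12):
            raise ValueError("negative genotype probability")
        if np.any(np.abs(self.probs.sum(axis=2) - 1.0) > 1e-9):
            raise ValueError("genotype triplets must sum to 1")

    def dosages(self) -> np.ndarray:
        return dosage(self.probs)


def switch_probabilities(genetic_cM: np.ndarray, n_ref: int, params: LSParams) -> np.ndarray:
    """Per-interval switch probability between adjacent typed sites."""
    d_morgan = np.diff(np.asarray(genetic_cM, dtype=np.float64)) / 100.0
    s = 1.0 - np.exp(-4.0 * params.ne_eff * d_morgan / n_ref)
    return np.maximum(s, params.min_switch)


def _emissions(targets: np.ndarray, panel_col: np.ndarray, lam: float) -> np.ndarray:
    """Emission matrix (B, H) at one typed site; missing observations emit 1."""
    obs = targets[:, None]
    e = np.where(obs == panel_col[None, :], 1.0 - lam, lam)
    return np.where(obs == MISSING, 1.0, e)


def _forward_backward(targets: np.ndarray, panel: np.ndarray,
                      s: np.ndarray, lam: float) -> np.ndarray:
    """Scaled forward-backward for a batch of target haplotypes.

    targets : (B, T) in {0, 1, MISSING}; panel : (H, T); s : (T-1,)
    returns posteriors gamma of shape (B, T, H), rows summing to 1.
    """
    B, T = targets.shape
    H = panel.shape[0]
    gamma = np.empty((B, T, H), dtype=np.float64)

    # forward pass (normalized alphas stored in gamma)
    alpha = _emissions(targets[:, 0], panel[:, 0], lam) / H
    alpha /= alpha.sum(axis=1, keepdims=True)
    gamma[:, 0] = alpha
    for t in range(1, T):
        st = s[t - 1]
        alpha = _emissions(targets[:, t], panel[:, t], lam) * (
            (1.0 - st) * alpha + st / H)
        alpha /= alpha.sum(axis=1, keepdims=True)
        gamma[:, t] = alpha

    # backward pass, combining into posteriors in place
    beta = np.ones((B, H), dtype=np.float64)
    for t in range(T - 2, -1, -1):
        st = s[t]
        eb = _emissions(targets[:, t + 1], panel[:, t + 1], lam) * beta
        beta = (1.0 - st) * eb + (st / H) * eb.sum(axis=1, keepdims=True)
        beta /= beta.sum(axis=1, keepdims=True)
        g = gamma[:, t] * beta
        gamma[:, t] = g / g.sum(axis=1, keepdims=True)
    return gamma


def _check_alleles(arr: np.ndarray, allow_missing: bool) -> None:
    ok = (arr == 0) | (arr == 1)
    if allow_missing:
        ok |= arr == MISSING
    if not np.all(ok):
        raise ValueError("alleles must be binary (0/1; -1 marks missing observations)")


def ls_posteriors(target_typed: np.ndarray, panel_typed: np.ndarray,
                  genetic_cM: np.ndarray, params: LSParams) -> np.ndarray:
    """Posterior copying probabilities for one target haplotype.

    Returns a (T, H) matrix; row ``j`` is the posterior over reference
    haplotypes at typed site ``j``.  The chain starts uniform over the H
    reference states.  Sites with target allele -1 are treated as missing
    (skipped: flat emission).
    """
    target = np.asarray(target_typed, dtype=np.int64)
    panel = np.asarray(panel_typed, dtype=np.int64)
    if target.ndim != 1 or target.size == 0:
        raise ValueError("need at least one typed site")
    if panel.ndim != 2 or panel.shape[1] != target.size:
        raise ValueError("panel must have shape (H, T)")
    _check_alleles(target, allow_missing=True)
    _check_alleles(panel, allow_missing=False)
    s = switch_probabilities(genetic_cM, panel.shape[0], params)
    return _forward_backward(target[None, :], panel, s, params.miscopy_lambda)[0]


def _interp_weights(typed_cM: np.ndarray, all_cM: np.ndarray,
                    typed_idx: np.ndarray):
    """For every site, the flanking typed-row indices (lo, hi) and the weight
    on the left row; typed sites map to themselves with weight 1."""
    L = all_cM.size
    j = np.searchsorted(typed_cM, all_cM, side="right") - 1
    lo = np.clip(j, 0, typed_cM.size - 1)
    hi = np.clip(j + 1, 0, typed_cM.size - 1)
    span = typed_cM[hi] - typed_cM[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(span > 0, (typed_cM[hi] - all_cM) / np.where(span > 0, span, 1.0), 1.0)
    w = np.clip(w, 0.0, 1.0)
    # typed sites use their own posterior exactly
    w[typed_idx] = 1.0
    lo[typed_idx] = np.arange(typed_idx.size)
    hi[typed_idx] = np.arange(typed_idx.size)
    return lo, hi, w


def interpolate_alleles(gamma: np.ndarray, panel_all: np.ndarray,
                        genetic_cM: np.ndarray, typed_idx: np.ndarray,
                        params: LSParams) -> np.ndarray:
    """Haploid P(allele = 1) at every panel site for one target haplotype.

    At typed sites the copying posterior is used directly; at untyped sites
    it is linearly interpolated in genetic distance between the flanking
    typed sites (nearest posterior beyond the ends), renormalized, and
    combined with the mis-copy probability:
    P = lambda + (1 - 2*lambda) * sum_h gamma_h * allele_h.
    """
    probs = _interpolated_dosage(gamma[None, :, :], panel_all,
                                 np.asarray(genetic_cM, dtype=np.float64),
                                 np.asarray(typed_idx, dtype=np.intp))[0]
    lam = params.miscopy_lambda
    return lam + (1.0 - 2.0 * lam) * probs


def _interpolated_dosage(gamma: np.ndarray, panel_all: np.ndarray,
                         all_cM: np.ndarray, typed_idx: np.ndarray) -> np.ndarray:
    """sum_h gamma_u(h) * allele_h(u) for every site u, batched over targets.

    gamma : (B, T, H); panel_all : (H, L); returns (B, L).
    """
    B, T, H = gamma.shape
    L = panel_all.shape[1]
    typed_cM = all_cM[typed_idx]
    lo, hi, w = _interp_weights(typed_cM, all_cM, typed_idx)
    out = np.empty((B, L), dtype=np.float64)
    A = panel_all.astype(np.float64)
    # group sites by their (lo, hi) typed bracket and use one matmul per group
    order = np.lexsort((hi, lo))
    lo_o, hi_o = lo[order], hi[order]
    bounds = np.flatnonzero(np.concatenate((
        [True], (lo_o[1:] != lo_o[:-1]) | (hi_o[1:] != hi_o[:-1]))))
    bounds = np.append(bounds, lo_o.size)
    for k in range(bounds.size - 1):
        sl = order[bounds[k]:bounds[k + 1]]
        jlo, jhi = int(lo_o[bounds[k]]), int(hi_o[bounds[k]])
        Au = A[:, sl]  # (H, n)
        dlo = gamma[:, jlo, :] @ Au  # (B, n)
        if jhi == jlo:
            out[:, sl] = dlo
        else:
            dhi = gamma[:, jhi, :] @ Au
            wk = w[sl][None, :]
            out[:, sl] = wk * dlo + (1.0 - wk) * dhi
    return out


def impute_haplotypes(targets_typed: np.ndarray, panel: HaplotypeSet,
                      typed_idx: np.ndarray, params: LSParams,
                      max_floats: float = 3.0e7) -> np.ndarray:
    """Haploid allele-1 probabilities at all panel sites for a batch of
    target haplotypes observed at the typed sites only.

    targets_typed : (B, T) alleles at ``panel.positions_bp[typed_idx]``.
    Returns (B, L) probabilities.  ``max_floats`` caps the posterior buffer
    (B_chunk * T * H) to bound memory.
    """
    targets = np.asarray(targets_typed, dtype=np.int64)
    if targets.ndim == 1:
        targets = targets[None, :]
    typed_idx = np.asarray(typed_idx, dtype=np.intp)
    if typed_idx.size == 0:
        raise ValueError("need at least one typed site")
    _check_alleles(targets, allow_missing=True)
    H = panel.n_haplotypes
    T = typed_idx.size
    panel_typed = panel.alleles[:, typed_idx].astype(np.int64)
    s = switch_probabilities(panel.positions_cM[typed_idx], H, params)
    lam = params.miscopy_lambda
    B = targets.shape[0]
    chunk = max(1, int(max_floats / max(T * H, 1)))
    out = np.empty((B, panel.n_sites), dtype=np.float64)
    for start in range(0, B, chunk):
        block = targets[start:start + chunk]
        gamma = _forward_backward(block, panel_typed, s, lam)
        dose = _interpolated_dosage(gamma, panel.alleles, panel.positions_cM,
                                    typed_idx)
        out[start:start + chunk] = lam + (1.0 - 2.0 * lam) * dose
    return out


def haploid_to_genotype(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Combine two haploid allele-1 probability vectors into genotype
    triplets (P(AA), P(Aa), P(aa)); shape (..., 3)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return np.stack([(1 - a) * (1 - b), a * (1 - b) + (1 - a) * b, a * b], axis=-1)


def impute_individual(hapA_typed: np.ndarray, hapB_typed: np.ndarray,
                      panel: HaplotypeSet, typed_idx: np.ndarray,
                      params: LSParams) -> np.ndarray:
    """Genotype-probability triplets at all panel sites for one individual
    whose two haplotypes are observed at the typed sites."""
    a = np.asarray(hapA_typed)
    b = np.asarray(hapB_typed)
    if a.shape != b.shape:
        raise ValueError("the two haplotypes must be typed at the same sites")
    probs = impute_haplotypes(np.stack([a, b]), panel, typed_idx, params)
    return haploid_to_genotype(probs[0], probs[1])


def impute_cohort(cohort_typed: HaplotypeSet, panel: HaplotypeSet,
                  params: LSParams) -> GenotypeProbs:
    """Impute every individual of a typed cohort against a reference panel.

    The cohort's sites must be a subset of the panel's sites (matched on
    bp position); output covers all panel sites.
    """
    typed_idx = np.searchsorted(panel.positions_bp, cohort_typed.positions_bp)
    if (np.any(typed_idx >= panel.n_sites)
            or np.any(panel.positions_bp[typed_idx] != cohort_typed.positions_bp)):
        raise ValueError("cohort typed sites must all be present in the panel")
    probs = impute_haplotypes(cohort_typed.alleles, panel, typed_idx, params)
    gp = haploid_to_genotype(probs[0::2], probs[1::2])
    return GenotypeProbs(gp, cohort_typed.individual_ids(), panel.positions_bp.copy())


def dosage(probs: np.ndarray) -> np.ndarray:
    """Expected alternate-allele dosage P(Aa) + 2 P(aa), in [0, 2]."""
    p = np.asarray(probs, dtype=np.float64)
    return p[..., 1] + 2.0 * p[..., 2]


def info_score(probs_site: np.ndarray) -> float:
    """IMPUTE-style INFO at one site over N individuals.

    With e_i = P_i(Aa) + 2 P_i(aa) and f_i = P_i(Aa) + 4 P_i(aa) and
    estimated frequency theta = sum(e) / 2N:
    info = 1 - sum(f - e^2) / (2 N theta (1 - theta)), set to 1 when
    theta is 0 or 1, clipped to [0, 1].
    """
    p = np.asarray(probs_site, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] == 0:
        raise ValueError("need genotype triplets for at least one individual")
    return float(info_scores(p[None].transpose(1, 0, 2))[0])


def info_scores(probs: np.ndarray) -> np.ndarray:
    """Vectorized INFO over sites; probs has shape (N, L, 3)."""
    p = np.asarray(probs, dtype=np.float64)
    if p.shape[0] == 0:
        raise ValueError("need at least one individual")
    N = p.shape[0]
    e = p[..., 1] + 2.0 * p[..., 2]
    f = p[..., 1] + 4.0 * p[..., 2]
    theta = e.sum(axis=0) / (2.0 * N)
    num = (f - e * e).sum(axis=0)
    denom = 2.0 * N * theta * (1.0 - theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        info = np.where(denom > 0, 1.0 - num / np.where(denom > 0, denom, 1.0), 1.0)
    return np.clip(info, 0.0, 1.0)


def merge_panels(panelA: HaplotypeSet, panelB: HaplotypeSet, mode: str,
                 params: LSParams | None = None) -> HaplotypeSet:
    """Merge two reference panels.

    ``intersect`` restricts both panels to their common sites and stacks the
    haplotypes.  ``cross_impute`` takes the site union: sites absent from
    one panel are imputed for each of that panel's haplotypes against the
    other panel and hard-called (allele 1 iff P > 0.5; ties to 0), mirroring
    the cross-imputation a production imputation engine performs when
    merging panels -- and the uncertainty it can introduce.
    """
    if mode not in ("intersect", "cross_impute"):
        raise ValueError("mode must be 'intersect' or 'cross_impute'")
    common, ia, ib = np.intersect1d(panelA.positions_bp, panelB.positions_bp,
                                    return_indices=True)
    if mode == "intersect":
        if common.size == 0:
            raise ValueError("panels share no sites; cannot intersect")
        return HaplotypeSet.concat_haplotypes(
            [panelA.take_sites(ia), panelB.take_sites(ib)])

    if params is None:
        params = LSParams()
    if common.size == 0:
        raise ValueError("panels share no sites; cross-imputation needs anchors")
    union = np.union1d(panelA.positions_bp, panelB.positions_bp)
    L = union.size
    posA = np.searchsorted(union, panelA.positions_bp)
    posB = np.searchsorted(union, panelB.positions_bp)
    cm = np.empty(L, dtype=np.float64)
    cm[posB] = panelB.positions_cM
    cm[posA] = panelA.positions_cM  # shared sites take A's coordinate

    def _fill(own: HaplotypeSet, own_cols: np.ndarray, other: HaplotypeSet,
              own_shared_idx: np.ndarray) -> np.ndarray:
        alleles = np.zeros((own.n_haplotypes, L), dtype=np.uint8)
        alleles[:, own_cols] = own.alleles
        missing_cols = np.setdiff1d(np.arange(L), own_cols)
        if missing_cols.size:
            typed_in_other = np.searchsorted(other.positions_bp,
                                             union[own_shared_cols_pos])
            probs = impute_haplotypes(own.alleles[:, own_shared_idx], other,
                                      typed_in_other, params)
            fill_in_other = np.searchsorted(other.positions_bp, union[missing_cols])
            alleles[:, missing_cols] = (probs[:, fill_in_other] > 0.5).astype(np.uint8)
        return alleles

    own_shared_cols_pos = np.searchsorted(union, common)
    allelesA = _fill(panelA, posA, panelB, ia)
    allelesB = _fill(panelB, posB, panelA, ib)
    return HaplotypeSet(
        np.vstack([allelesA, allelesB]), union, cm,
        np.concatenate([panelA.sample_ids, panelB.sample_ids]),
        np.concatenate([panelA.populations, panelB.populations]))


def leave_one_out_impute(cohort: HaplotypeSet, panel: HaplotypeSet,
                         typed_idx: np.ndarray, params: LSParams) -> GenotypeProbs:
    """Impute each cohort individual after removing its own two haplotypes
    from the reference panel (the cohort must be contained in the panel).

    ``cohort`` carries truth alleles at all panel sites; only the columns in
    ``typed_idx`` are exposed to the engine.
    """
    typed_idx = np.asarray(typed_idx, dtype=np.intp)
    if not np.array_equal(cohort.positions_bp, panel.positions_bp):
        raise ValueError("cohort and panel must share the same site set")
    panel_ids = panel.sample_ids
    out = np.empty((cohort.n_individuals, panel.n_sites, 3), dtype=np.float64)
    for i, sid in enumerate(cohort.individual_ids()):
        keep = np.flatnonzero(panel_ids != sid)
        if keep.size == panel.n_haplotypes:
            raise ValueError(f"individual {sid!r} not found in the reference panel")
        reduced = panel.take_haplotypes(keep)
        hapA = cohort.alleles[2 * i, typed_idx]
        hapB = cohort.alleles[2 * i + 1, typed_idx]
        out[i] = impute_individual(hapA, hapB, reduced, typed_idx, params)
    return GenotypeProbs(out, cohort.individual_ids(), panel.positions_bp.copy())
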