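"""File formats: phased VCF, ancestry-tracks TSV, array site lists,
accuracy tables, manifests and YAML configs.

Internal coordinates are 0-based half-open; the VCF boundary converts to
1-based.  Haplotype VCFs carry phased GT plus a ``##SAMPLE`` header line
per sample recording its population label; imputed VCFs carry GP (genotype
probability triplet), DS (dosage) and a per-site INFO score.  Reading goes
through cyvcf2; writing emits the text directly.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .arraydesign import ArrayScheme
from .hmm import GenotypeProbs
from .sim import AncestryTracks, ChromosomeSpec, HaplotypeSet

CONTIG = "chrSIM"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_haplotype_vcf(path, haps: HaplotypeSet, contig: str = CONTIG,
                        contig_length: int | None = None) -> None:
    """Write phased biallelic haplotypes as VCF v4.2 (GT with '|')."""
    ids = haps.individual_ids()
    pops = haps.populations[0::2]
    length = contig_length if contig_length is not None else (
        int(haps.positions_bp[-1]) + 1 if haps.n_sites else 1)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=admiximpute",
        f"##contig=<ID={contig},length={length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##SAMPLE=<ID={sid},Population={pop}>" for sid, pop in zip(ids, pops)]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids))
    a = haps.alleles
    gt = np.char.add(np.char.add(a[0::2].astype("U1"), "|"), a[1::2].astype("U1"))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for j in range(haps.n_sites):
            pos1 = int(haps.positions_bp[j]) + 1
            fh.write(f"{contig}\t{pos1}\tsite{j}\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(gt[:, j]) + "\n")


def read_haplotype_vcf(path, chrom: ChromosomeSpec) -> HaplotypeSet:
    """Read a phased biallelic VCF into a HaplotypeSet; genetic coordinates
    are recomputed from ``chrom``'s map.  Unphased or multi-allelic records
    are rejected with the offending position."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pops = {m.group(1): m.group(2) for m in re.finditer(
        r"##SAMPLE=<ID=([^,>]+),Population=([^,>]+)>", vcf.raw_header)}
    positions, cols = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"{path}: site at position {v.POS} is not biallelic")
        g = np.array(v.genotypes)
        if g.shape[1] < 3 or not np.all(g[:, 2]):
            raise ValueError(f"{path}: unphased genotype at position {v.POS}")
        if np.any(g[:, :2] < 0) or np.any(g[:, :2] > 1):
            raise ValueError(f"{path}: missing or non-binary allele at position {v.POS}")
        positions.append(v.POS - 1)
        cols.append(g[:, :2].reshape(-1))
    vcf.close()
    alleles = np.array(cols, dtype=np.uint8).T if cols else np.zeros((2 * len(samples), 0), np.uint8)
    pos = np.asarray(positions, dtype=np.int64)
    sample_ids = np.repeat(samples, 2)
    populations = np.array([pops.get(s, "NA") for s in sample_ids])
    out = HaplotypeSet(alleles, pos, chrom.bp_to_cM(pos), sample_ids, populations)
    out.validate()
    return out


def write_imputed_vcf(path, gp: GenotypeProbs, info: np.ndarray,
                      contig: str = CONTIG, precision: int = 17) -> None:
    """Write imputed genotype probabilities as VCF with GP and DS FORMAT
    fields and a per-site INFO score.  Full float precision by default so
    that downstream evaluation from file matches in-memory evaluation."""
    ids = list(gp.sample_ids)
    fmt = f"%.{precision}g"
    lines = [
        "##fileformat=VCFv4.2",
        "##source=admiximpute",
        f"##contig=<ID={contig}>",
        '##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation certainty">',
        '##FORMAT=<ID=GP,Number=3,Type=Float,Description="P(AA),P(Aa),P(aa)">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids),
    ]
    dose = gp.dosages()
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for j in range(gp.probs.shape[1]):
            pos1 = int(gp.positions_bp[j]) + 1
            cells = [
                ",".join(fmt % p for p in gp.probs[i, j]) + ":" + fmt % dose[i, j]
                for i in range(len(ids))
            ]
            fh.write(f"{contig}\t{pos1}\tsite{j}\tA\tG\t.\tPASS\t"
                     f"INFO={fmt % info[j]}\tGP:DS\t" + "\t".join(cells) + "\n")


def read_imputed_vcf(path) -> tuple[GenotypeProbs, np.ndarray]:
    """Read a GP/DS VCF back into GenotypeProbs and the per-site INFO array.

    The body is parsed textually rather than through htslib: VCF FORMAT
    floats are 32-bit in htslib, which would quantize the probabilities and
    break the exact equivalence between file-based and in-memory
    evaluation.
    """
    samples: list[str] = []
    positions, gps, infos = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            positions.append(int(fields[1]) - 1)
            m = re.search(r"INFO=([^;]+)", fields[7])
            if m is None:
                raise ValueError(f"{path}: missing INFO score at position {fields[1]}")
            infos.append(float(m.group(1)))
            gp_index = fields[8].split(":").index("GP")
            gps.append([
                [float(x) for x in cell.split(":")[gp_index].split(",")]
                for cell in fields[9:]
            ])
    probs = (np.array(gps, dtype=np.float64).transpose(1, 0, 2)
             if gps else np.zeros((len(samples), 0, 3)))
    gp = GenotypeProbs(probs, np.array(samples),
                       np.asarray(positions, dtype=np.int64))
    return gp, np.asarray(infos, dtype=np.float64)


# ---------------------------------------------------------------------------
# Tracks TSV (BED-like, 0-based half-open)
# ---------------------------------------------------------------------------

def write_tracks_tsv(path, tracks: AncestryTracks) -> None:
    tracks.to_frame().to_csv(path, sep="\t", index=False)


def read_tracks_tsv(path, length_bp: int | None = None) -> AncestryTracks:
    """Read an ancestry-tracks TSV (haplotype_id, start_bp, end_bp, ancestry;
    header required).  Haplotype ids must end in _1/_2 and pair up."""
    df = pd.read_csv(path, sep="\t")
    required = ["haplotype_id", "start_bp", "end_bp", "ancestry"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"{path}: tracks TSV must start with columns {required}")
    if length_bp is None:
        length_bp = int(df["end_bp"].max())
    hap_ids = list(dict.fromkeys(df["haplotype_id"]))
    starts, ends, labels, sample_ids = [], [], [], []
    for hid in hap_ids:
        sub = df[df["haplotype_id"] == hid].sort_values("start_bp")
        starts.append(sub["start_bp"].to_numpy(np.int64))
        ends.append(sub["end_bp"].to_numpy(np.int64))
        labels.append(sub["ancestry"].to_numpy(object))
        if not re.search(r"_[12]$", str(hid)):
            raise ValueError(f"{path}: haplotype id {hid!r} must end in _1 or _2")
        sample_ids.append(re.sub(r"_[12]$", "", str(hid)))
    tracks = AncestryTracks(length_bp, starts, ends, labels, np.asarray(sample_ids))
    tracks.validate()
    return tracks


# ---------------------------------------------------------------------------
# Array site list + sidecar
# ---------------------------------------------------------------------------

def write_site_list(path, haps: HaplotypeSet, scheme: ArrayScheme) -> None:
    """One 1-based bp position per line, plus a JSON sidecar with the
    ascertainment metadata (<path>.json)."""
    pos1 = haps.positions_bp[scheme.typed_site_indices] + 1
    Path(path).write_text("\n".join(str(int(p)) for p in pos1) + "\n")
    meta = {
        "ascertainment_pop": scheme.ascertainment_pop,
        "target_mean_spacing_bp": scheme.target_mean_spacing_bp,
        "maf_bin_edges": list(scheme.maf_bin_edges),
        "maf_bin_proportions": list(scheme.maf_bin_proportions),
        "seed": scheme.seed,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_site_list(path, haps: HaplotypeSet) -> ArrayScheme:
    """Rebuild an ArrayScheme from a site-list file against a haplotype set
    (every listed position must exist in the set)."""
    pos1 = np.array([int(x) for x in Path(path).read_text().split()], dtype=np.int64)
    idx = np.searchsorted(haps.positions_bp, pos1 - 1)
    bad = (idx >= haps.n_sites) | (haps.positions_bp[np.clip(idx, 0, haps.n_sites - 1)] != pos1 - 1)
    if np.any(bad):
        raise ValueError(f"{path}: position {int(pos1[np.argmax(bad)])} not present "
                         "in the haplotype set")
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return ArrayScheme(
        np.sort(idx),
        meta.get("ascertainment_pop", "ALL"),
        float(meta.get("target_mean_spacing_bp", 0.0) or 0.0),
        tuple(meta.get("maf_bin_edges", (0.0, 0.5))),
        tuple(meta.get("maf_bin_proportions", (1.0,))),
        int(meta.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# Tables, manifests, config
# ---------------------------------------------------------------------------

def write_accuracy_tsv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_accuracy_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str) + "\n")


CONFIG_KEYS = {
    "seed", "scale", "added_sizes", "length_bp", "rate_cM_per_Mb", "n_sites",
    "n_afr_panel", "n_eur_panel", "n_adm_panel", "n_targets",
    "donor_haps_per_ancestry", "n_founders", "founder_switch_rate",
    "mutation_flip_rate", "divergence_F", "proportions", "generations_ago",
    "ascertainment_pop", "target_spacing_bp", "maf_bin_edges",
    "maf_bin_proportions", "nat_pool_size", "ls", "bins", "threshold",
    "r2_mode",
}
LS_KEYS = {"ne_eff", "miscopy_lambda", "min_switch"}
BIN_KEYS = {"breakpoints", "names"}
THRESHOLD_KEYS = {"min_maf", "min_info"}


def load_config(path) -> dict:
    """Load and schema-validate a YAML run config; unknown keys are
    rejected by name."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key in cfg:
        if key not in CONFIG_KEYS:
            raise ValueError(f"{path}: unknown config key {key!r}")
    for sub, allowed in (("ls", LS_KEYS), ("bins", BIN_KEYS),
                         ("threshold", THRESHOLD_KEYS)):
        for key in (cfg.get(sub) or {}):
            if key not in allowed:
                raise ValueError(f"{path}: unknown config key {sub}.{key!r}")
    if "seed" not in cfg:
        raise ValueError(f"{path}: missing required config key 'seed'")
    return cfg
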