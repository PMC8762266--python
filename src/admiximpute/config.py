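"""Resolve a validated config mapping into typed run objects."""

from __future__ import annotations

from dataclasses import fields

from .evaluation import ExperimentConfig, QualityThreshold
from .hmm import LSParams
from .strata import FreqBins

_EXP_FIELDS = {f.name for f in fields(ExperimentConfig)} - {"ls"}
_TUPLE_FIELDS = {"added_sizes", "divergence_F", "proportions",
                 "maf_bin_edges", "maf_bin_proportions"}


def resolve_config(cfg: dict) -> dict:
    """Build ExperimentConfig / LSParams / FreqBins / QualityThreshold from
    a config mapping (already schema-validated by ``io.load_config``).

    ``scale`` derives panel sizes from the full-scale ratios; explicit count
    keys override the scaled values.
    """
    ls = LSParams(**(cfg.get("ls") or {}))
    overrides = {k: (tuple(v) if k in _TUPLE_FIELDS and v is not None else v)
                 for k, v in cfg.items() if k in _EXP_FIELDS}
    if "scale" in cfg and cfg["scale"] is not None:
        sizes = overrides.pop("added_sizes", (0, 20, 50, 100))
        exp = ExperimentConfig.at_scale(cfg["scale"], sizes, ls=ls, **overrides)
    else:
        exp = ExperimentConfig(ls=ls, **overrides)
    bins_cfg = cfg.get("bins") or {}
    bins = FreqBins(tuple(bins_cfg["breakpoints"]), tuple(bins_cfg["names"])) \
        if bins_cfg else FreqBins()
    thr = QualityThreshold(**(cfg.get("threshold") or {}))
    return {
        "seed": int(cfg["seed"]),
        "experiment": exp,
        "bins": bins,
        "threshold": thr,
        "r2_mode": cfg.get("r2_mode", "pooled"),
    }
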