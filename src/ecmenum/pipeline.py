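"""Top-level pipeline: read -> preprocess -> enumerate -> un-split -> report.

Stage order: split reversible reactions, hide/tag (on original metabolite
and reaction ids), split bidirectional externals, optional compression,
enumeration (direct or indirect), un-splitting, normalization, optional
validation.  Hiding runs before external splitting so that a bidirectional
metabolite can be hidden under its original id.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Optional, Sequence

from . import io as io_mod
from .direct import enumerate_direct, IntersectionStats
from .fixtures import build_fixture
from .indirect import enumerate_indirect
from .network import MetabolicNetwork
from .postprocess import (
    ECMSet,
    is_steady_state_conversion,
    is_elementary_in_set,
    normalize_ecms,
    unsplit_externals,
)
from .preprocess import (
    DEFAULT_COMPRESSION_ORDER,
    UsageError,
    compress_network,
    hide_metabolites,
    split_bidirectional_externals,
    split_reversible,
    tag_reactions,
)


@dataclass
class PipelineConfig:
    network: Optional[MetabolicNetwork] = None
    model_path: Optional[str] = None
    matrix_path: Optional[str] = None
    annotations_path: Optional[str] = None
    fixture: Optional[str] = None
    method: str = "direct"  # or "indirect"
    hide: Sequence[str] = ()
    tag: Sequence[str] = ()
    compress: bool = True
    compression_steps: Sequence[int] = DEFAULT_COMPRESSION_ORDER
    normalize: str = "coprime_integer"
    biomass_id: Optional[str] = None
    order: Sequence[str] | str = "auto"
    max_intermediate: Optional[int] = None
    verify: bool = False
    out: Optional[str] = None
    out_format: str = "csv"
    rendering: str = "rational"
    external_policy: Optional[dict] = None
    seed: Optional[int] = None


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _load(cfg: PipelineConfig) -> MetabolicNetwork:
    sources = [cfg.network, cfg.model_path, cfg.matrix_path, cfg.fixture]
    if sum(s is not None for s in sources) != 1:
        raise UsageError("specify exactly one of network, model_path, matrix_path, fixture")
    if cfg.network is not None:
        return cfg.network
    if cfg.fixture:
        return build_fixture(cfg.fixture)
    if cfg.matrix_path:
        if not cfg.annotations_path:
            raise UsageError("matrix_path needs annotations_path")
        return io_mod.read_table_network(cfg.matrix_path, cfg.annotations_path)
    return io_mod.read_sbml(cfg.model_path, cfg.external_policy)


def run_pipeline(cfg: PipelineConfig) -> tuple[ECMSet, dict]:
    """Execute the full enumeration pipeline; returns (ECMSet, report)."""
    report: dict = {"stages": [], "config": {"method": cfg.method, "seed": cfg.seed}}

    def stage(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kw)
        except Exception as e:  # annotate failures with the stage name
            raise PipelineError(name, e) from e
        report["stages"].append({"stage": name, "seconds": time.perf_counter() - t0})
        return result

    net = stage("read", _load, cfg)
    report["model"] = {
        "metabolites": len(net.metabolites),
        "reactions": len(net.reactions),
        "internal": len(net.internal_ids),
    }
    net = stage("split_reversible", split_reversible, net)
    if cfg.hide:
        net = stage("hide", hide_metabolites, net, list(cfg.hide))
    if cfg.tag:
        net = stage("tag", tag_reactions, net, list(cfg.tag))
    validation_net = net
    net = stage("split_externals", split_bidirectional_externals, net)
    if cfg.compress:
        net = stage("compress", compress_network, net, cfg.compression_steps)
        report["compressed"] = {
            "metabolites": len(net.metabolites),
            "reactions": len(net.reactions),
        }

    if cfg.method == "direct":
        stats: list[IntersectionStats] = []
        R = stage("enumerate_direct", enumerate_direct, net, cfg.order, stats)
        report["iterations"] = [
            {"metabolite": s.metabolite, "in": s.n_plus + s.n_zero + s.n_minus,
             "candidates": s.n_candidates, "redundant": s.n_redundant, "out": s.n_out}
            for s in stats
        ]
    elif cfg.method == "indirect":
        log: list[str] = []
        R = stage("enumerate_indirect", enumerate_indirect, net,
                  cfg.max_intermediate, log)
        report["dd_stages"] = log
    else:
        raise UsageError(f"unknown method {cfg.method!r}")

    ecms = stage("unsplit", unsplit_externals, R, net)
    biomass = cfg.biomass_id or net.metadata.get("biomass")
    ecms.biomass_id = biomass
    ecms = stage("normalize", normalize_ecms, ecms, cfg.normalize, biomass)
    report["n_ecms"] = len(ecms)

    if cfg.verify:
        ok1 = all(is_steady_state_conversion(c, validation_net)[0]
                  for c in ecms.conversions)
        ok2 = all(is_elementary_in_set(c, ecms) for c in ecms.conversions)
        report["verify"] = {"steady_state": ok1, "elementary": ok2}

    if cfg.out:
        stage("write", io_mod.write_ecms, ecms, cfg.out, cfg.out_format, cfg.rendering)
    return ecms, report
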