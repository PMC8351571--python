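"""Orchestrate the default correction run.

Default order: (1) align every cluster lacking an MSA; (2) in tandem on the
*original* clusters, evaluate defragmentation round 1 and the profile-based
cluster merge — neither sees the other's edits; (3) combine: apply the merge
partition, then apply round-1 fusions inside the merged clusters, and
realign what changed; (4) run defragmentation round 2 on the combined
clusters, which catches fragments whose pieces started out in different
clusters; (5) summarise the core/SCG genome, classify fragmentation causes,
and write all reports.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import aligner as _aligner
from . import defrag as _defrag
from . import fragclass as _fragclass
from . import io as _io
from . import merge as _merge
from . import scg as _scg
from .model import FragmentPair, InputError, PangenomeState, StageError
from .scoring import ScoringParams

log = logging.getLogger("panfix")


@dataclass
class PipelineOptions:
    """Thresholds and backends for one run; all CLI-configurable."""

    relbit_thr: float = _defrag.DEFAULT_RELBIT
    overlap_thr: float = _defrag.DEFAULT_OVERLAP
    abs_min_bit: Optional[float] = None
    strict_selfbit: bool = False
    end_margin: int = _fragclass.DEFAULT_END_MARGIN
    indel_max_gap: int = _fragclass.DEFAULT_INDEL_MAX_GAP
    scoring: ScoringParams = field(default_factory=ScoringParams)
    aligner_backend: str = "internal"
    external_aligner_cmd: Optional[Sequence[str]] = None

    def validate(self) -> None:
        if not (0 <= self.relbit_thr) or not (0 <= self.overlap_thr <= 1):
            raise InputError("relbit/percoverlap thresholds out of range")
        if self.end_margin < 0 or self.indel_max_gap < 0:
            raise InputError("fragclass margins must be non-negative")


@dataclass
class PipelineResult:
    state: PangenomeState
    summary: Optional[_scg.CoreSummary] = None
    partition: Dict[str, str] = field(default_factory=dict)


def _log_options(options: PipelineOptions) -> None:
    log.info(
        "thresholds: relbit=%s percoverlap=%s abs_min_bit=%s strict_selfbit=%s "
        "end_margin=%s indel_max_gap=%s gap_open=%s gap_extend=%s matrix=%s",
        options.relbit_thr, options.overlap_thr, options.abs_min_bit,
        options.strict_selfbit, options.end_margin, options.indel_max_gap,
        options.scoring.gap_open, options.scoring.gap_extend,
        options.scoring.matrix_name,
    )


def align_missing(state: PangenomeState, options: PipelineOptions) -> None:
    missing = [c for c in sorted(state.clusters) if c not in state.msas]
    _aligner.realign_affected(
        state, missing, options.scoring,
        backend=options.aligner_backend,
        external_cmd=options.external_aligner_cmd,
    )


def evaluate_defrag(
    state: PangenomeState, options: PipelineOptions, round_no: int
) -> List[FragmentPair]:
    pairs: List[FragmentPair] = []
    for cid in _defrag.find_duplicate_clusters(state):
        pairs.extend(
            _defrag.call_fragments(
                state, cid, options.relbit_thr, options.overlap_thr,
                round_no, options.scoring,
            )
        )
    state.fragment_pairs.extend(pairs)
    return pairs


def evaluate_merge(
    state: PangenomeState, options: PipelineOptions
) -> Tuple[Dict[str, str], List[_merge.HitEdge]]:
    """Profiles and selfbits from the current (original) clusters only."""
    assignment = state.assignment()
    profiles = []
    for cid in sorted(state.clusters):
        msa = state.msas.get(cid)
        if msa is None:
            raise StageError("merge", "cluster has no MSA", [cid])
        profile = _merge.build_profile(msa)
        members = [state.calls[g] for g in sorted(state.clusters[cid])]
        profiles.append(_merge.compute_selfbit(profile, members))
    calls = list(state.live_calls().values())
    edges = _merge.build_hit_edgelist(
        calls, profiles, assignment,
        abs_min_bit=options.abs_min_bit,
        strict_selfbit=options.strict_selfbit,
    )
    partition = _merge.merge_components(sorted(state.clusters), edges, assignment)
    return partition, edges


def apply_merge(state: PangenomeState, partition: Dict[str, str]) -> List[str]:
    """Union the members of each merged component; returns changed clusters.

    Old per-cluster MSAs are kept around (fusion ordering may still consult
    them) but merged clusters are marked stale for re-alignment.
    """
    groups: Dict[str, List[str]] = {}
    for old, new in partition.items():
        groups.setdefault(new, []).append(old)
    changed: List[str] = []
    new_clusters: Dict[str, set] = {}
    for new, olds in groups.items():
        members = set()
        for old in olds:
            members |= state.clusters[old]
        new_clusters[new] = members
        if len(olds) > 1:
            changed.append(new)
    state.clusters = new_clusters
    state.merge_map = dict(partition)
    for cid in changed:
        state.msas.pop(cid, None)
        state.stale.add(cid)
    return sorted(changed)


def apply_round_fusions(
    state: PangenomeState,
    pairs: List[FragmentPair],
    cluster_map: Optional[Dict[str, str]] = None,
) -> List[str]:
    return _defrag.apply_fusions(state, pairs, cluster_map=cluster_map)


def run_full(state: PangenomeState, options: Optional[PipelineOptions] = None) -> PipelineResult:
    """The default end-to-end correction run (deterministic given inputs)."""
    options = options or PipelineOptions()
    options.validate()
    _log_options(options)
    t0 = time.perf_counter()

    _stage("align", align_missing, state, options)
    pairs1 = _stage("defrag-1", evaluate_defrag, state, options, 1)
    partition, _ = _stage("merge", evaluate_merge, state, options)
    _stage("combine", apply_merge, state, partition)
    _stage("combine", apply_round_fusions, state, pairs1, partition)
    _stage("realign", _realign_stale, state, options)
    pairs2 = _stage("defrag-2", evaluate_defrag, state, options, 2)
    _stage("defrag-2", apply_round_fusions, state, pairs2)
    _stage("realign", _realign_stale, state, options)
    _stage(
        "fragclass", _fragclass.classify_fusions, state,
        options.end_margin, options.indel_max_gap,
    )
    summary = _stage("scg", _scg.core_summary, state)
    log.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return PipelineResult(state, summary, partition)


def run_merge_only(state: PangenomeState, options: Optional[PipelineOptions] = None) -> PipelineResult:
    options = options or PipelineOptions()
    options.validate()
    _log_options(options)
    _stage("align", align_missing, state, options)
    partition, _ = _stage("merge", evaluate_merge, state, options)
    _stage("combine", apply_merge, state, partition)
    _stage("realign", _realign_stale, state, options)
    summary = _stage("scg", _scg.core_summary, state)
    return PipelineResult(state, summary, partition)


def run_defrag_only(state: PangenomeState, options: Optional[PipelineOptions] = None) -> PipelineResult:
    options = options or PipelineOptions()
    options.validate()
    _log_options(options)
    _stage("align", align_missing, state, options)
    pairs = _stage("defrag-1", evaluate_defrag, state, options, 1)
    _stage("defrag-1", apply_round_fusions, state, pairs)
    _stage("realign", _realign_stale, state, options)
    _stage(
        "fragclass", _fragclass.classify_fusions, state,
        options.end_margin, options.indel_max_gap,
    )
    summary = _stage("scg", _scg.core_summary, state)
    return PipelineResult(state, summary, {})


def _realign_stale(state: PangenomeState, options: PipelineOptions) -> None:
    _aligner.realign_affected(
        state, sorted(state.stale), options.scoring,
        backend=options.aligner_backend,
        external_cmd=options.external_aligner_cmd,
    )


def _stage(name: str, fn, *args):
    t0 = time.perf_counter()
    try:
        out = fn(*args)
    except (InputError, StageError):
        raise
    except Exception as exc:  # pragma: no cover - defensive wrapping
        raise StageError(name, str(exc)) from exc
    log.info("stage %-10s %.2f s", name, time.perf_counter() - t0)
    return out


# --------------------------------------------------------------------------
# file-level entry point


@dataclass
class PipelineConfig:
    """Paths plus options for a file-based run (mirrors the CLI flags)."""

    gene_calls: str
    coords: str
    outdir: str
    clusters: Optional[str] = None
    cluster_dialect: str = "generic-3col"
    coords_one_based: bool = False
    mode: str = "full"
    minbit: float = 0.35
    options: PipelineOptions = field(default_factory=PipelineOptions)


def run_files(config: PipelineConfig) -> PipelineResult:
    """Read inputs, run the requested mode, write every report."""
    if config.mode not in ("full", "merge-only", "defrag-only"):
        raise InputError(f"unknown mode {config.mode!r}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        calls, genomes = _io.read_gene_calls(
            config.gene_calls, config.coords, one_based=config.coords_one_based
        )
        state = PangenomeState(calls=calls, genomes=genomes)
        if config.clusters:
            assignment = _io.read_cluster_table(
                config.clusters, config.cluster_dialect, all_call_ids=calls
            )
            unknown = sorted(set(assignment) - set(calls))
            if unknown:
                raise InputError(f"cluster table lists unknown gene calls: {unknown}")
        else:
            log.info("no cluster table given; bootstrap clustering at minbit %.2f",
                     config.minbit)
            from .scoring import bootstrap_clusters

            assignment = bootstrap_clusters(
                calls.values(), config.options.scoring, config.minbit
            )
        for g, c in assignment.items():
            state.clusters.setdefault(c, set()).add(g)

        runner = {
            "full": run_full,
            "merge-only": run_merge_only,
            "defrag-only": run_defrag_only,
        }[config.mode]
        result = runner(state, config.options)
        _io.write_reports(result.state, out)
        _scg.write_scg_outputs(result.state, out)
        return result
    finally:
        log.removeHandler(handler)
        handler.close()
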