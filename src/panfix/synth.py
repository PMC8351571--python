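"""Synthetic phage pangenomes with planted ground truth.

The generator emulates, at desk scale, the phenomena the pipeline corrects:

* gene families whose members diverged by substitution only (no indels),
* families split into two clusters because cross-subfamily pairwise
  similarity falls below the clustering threshold even though shared motif
  blocks remain detectable by cluster profiles,
* fragmented gene calls from each cause — a frameshift indel (pieces nearly
  adjacent), an inserted selfish-element ORF (pieces separated by the
  element's own gene call), and splitting across the reported genome's ends,
* true paralog duplicates that must never be fused.

Sequences are amino acids only; genome coordinates are bookkeeping (3 bp
per residue) laid out so that the fragment-cause classifier's default
margins hold by construction. Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .model import AA_ORDER, GeneCall, GenomeRecord, InputError, PangenomeState
from .scoring import BLOSUM62_BACKGROUND, ScoringParams, load_matrix

_BP_PER_AA = 3


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic pangenome.

    Defaults describe a 20-genome, 40-family phage-like set with five
    planted fragments per cause, three split families at ~28%
    cross-subfamily identity, and three true-paralog decoys.
    """

    n_genomes: int = 20
    n_families: int = 40
    member_identity: float = 0.85  # member-to-ancestor, per site
    n_split_families: int = 3
    n_frameshift: int = 5
    n_element: int = 5
    n_end_split: int = 5
    n_paralog_decoys: int = 3
    n_round2_fragments: int = 0  # fragments whose pieces start in the two
    # clusters of a split family; only resolvable after merging
    min_len: int = 80
    max_len: int = 400
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.member_identity < 1.0):
            raise InputError("member_identity must lie in (0, 1)")
        counts = [
            self.n_genomes, self.n_families, self.n_split_families,
            self.n_frameshift, self.n_element, self.n_end_split,
            self.n_paralog_decoys, self.n_round2_fragments,
        ]
        if any(c < 0 for c in counts):
            raise InputError("all fixture counts must be non-negative")
        used = (
            self.n_split_families + self.n_frameshift + self.n_element
            + self.n_end_split + self.n_paralog_decoys
        )
        if used > self.n_families:
            raise InputError(
                f"planted events need {used} families but only "
                f"{self.n_families} exist"
            )
        if self.n_end_split > self.n_genomes:
            raise InputError("at most one end-split event per genome")
        if self.n_round2_fragments > self.n_split_families:
            raise InputError("round-2 fragments are planted in split families")
        if self.n_split_families and self.n_genomes < 4:
            raise InputError("split families need at least 4 genomes")
        if self.n_round2_fragments and self.n_genomes < 6:
            raise InputError("round-2 fragments need at least 6 genomes")
        if self.min_len < 60 or self.max_len <= self.min_len:
            raise InputError("need 60 <= min_len < max_len")


@dataclass
class PlantedFragment:
    family: str
    genome: str
    n_id: str
    c_id: str
    cause: str
    round: int  # 1: detectable immediately; 2: only after cluster merging


@dataclass
class TruthManifest:
    """Everything the generator planted, for scoring pipeline output."""

    families: Dict[str, List[str]]
    ancestors: Dict[str, str]
    fragments: List[PlantedFragment]
    split_families: List[Tuple[str, str, str]]  # family, cluster_a, cluster_b
    decoys: List[Tuple[str, str, str]]  # family, genome, decoy call id
    scg_before: List[str]
    scg_after: List[str]


class _Sampler:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        mat = load_matrix("BLOSUM62")
        s = np.array([[mat[a, b] for b in AA_ORDER] for a in AA_ORDER])
        # substitution kernel: replacement residue b given a drawn with
        # probability ~ background(b) * 2^(S62(a,b)/2), never b == a, so
        # diverged members stay recognisable to profiles
        cond = BLOSUM62_BACKGROUND[None, :] * np.power(2.0, s / 2.0)
        np.fill_diagonal(cond, 0.0)
        self.cond = cond / cond.sum(axis=1, keepdims=True)

    def protein(self, length: int) -> str:
        codes = self.rng.choice(20, size=length, p=BLOSUM62_BACKGROUND)
        return "".join(AA_ORDER[c] for c in codes)

    def mutate(self, seq: str, identity: float) -> str:
        """Per-site substitution so realized identity ~ target in expectation."""
        out = list(seq)
        hit = self.rng.random(len(seq)) < (1.0 - identity)
        for i in np.flatnonzero(hit):
            a = AA_ORDER.index(seq[i])
            out[i] = AA_ORDER[self.rng.choice(20, p=self.cond[a])]
        return "".join(out)


def _identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def generate(config: FixtureConfig) -> Tuple[PangenomeState, TruthManifest]:
    """Build one synthetic pangenome plus its truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sampler = _Sampler(rng)

    genomes = [f"g{i:02d}" for i in range(config.n_genomes)]
    families = [f"F{i:03d}" for i in range(config.n_families)]
    cursor = 0
    split_fams = families[cursor: cursor + config.n_split_families]
    cursor += config.n_split_families
    frame_fams = families[cursor: cursor + config.n_frameshift]
    cursor += config.n_frameshift
    element_fams = families[cursor: cursor + config.n_element]
    cursor += config.n_element
    end_fams = families[cursor: cursor + config.n_end_split]
    cursor += config.n_end_split
    decoy_fams = families[cursor: cursor + config.n_paralog_decoys]
    cursor += config.n_paralog_decoys

    state = PangenomeState()
    manifest = TruthManifest({}, {}, [], [], [], [], [])
    assignment: Dict[str, str] = {}
    # genome -> ordered layout units; each unit is a list of
    # (call_id, aa_seq, gap_before_bp)
    layout: Dict[str, List[List[Tuple[str, str, int]]]] = {g: [] for g in genomes}
    pinned_start: Dict[str, Tuple[str, str]] = {}
    pinned_end: Dict[str, Tuple[str, str]] = {}

    def plain_family(fam: str) -> Dict[str, str]:
        length = int(rng.integers(config.min_len, config.max_len + 1))
        ancestor = sampler.protein(length)
        manifest.ancestors[fam] = ancestor
        members = {g: sampler.mutate(ancestor, config.member_identity) for g in genomes}
        manifest.families[fam] = [f"{g}|{fam}" for g in genomes]
        return members

    # --- regular, fragment-host and decoy families -------------------------
    split_set = set(split_fams)
    member_seqs: Dict[str, Dict[str, str]] = {}
    for fam in families:
        if fam in split_set:
            continue
        member_seqs[fam] = plain_family(fam)
        for g in genomes:
            assignment[f"{g}|{fam}"] = fam

    # --- split families: motif blocks + subfamily-specific linkers ---------
    half = config.n_genomes // 2
    for k, fam in enumerate(split_fams):
        # conserved motif blocks shared family-wide, linkers specific to each
        # subfamily and internally diverse; one *partial* member per
        # subfamily (a truncated call spanning two motifs) keeps the
        # cluster's selfbit threshold at conserved-core level, the way real
        # mergeable clusters carry short or highly diverged members
        n_motifs, motif_len = 4, 22
        motifs = [sampler.protein(motif_len) for _ in range(n_motifs)]
        linker_lens = [int(rng.integers(12, 31)) for _ in range(n_motifs + 1)]
        sub_linkers = {
            "a": [sampler.protein(l) for l in linker_lens],
            "b": [sampler.protein(l) for l in linker_lens],
        }
        manifest.split_families.append((fam, f"{fam}a", f"{fam}b"))
        manifest.families[fam] = []
        for gi, g in enumerate(genomes):
            sub = "a" if gi < half else "b"
            links = [sampler.mutate(l, 0.55) for l in sub_linkers[sub]]
            mots = [sampler.mutate(m, 0.95) for m in motifs]
            seq = links[0]
            for m, l in zip(mots, links[1:]):
                seq += m + l
            partial = gi == (half - 1 if sub == "a" else config.n_genomes - 1)
            if partial:
                lo = linker_lens[0]
                hi = lo + motif_len + linker_lens[1] + motif_len
                seq = seq[lo:hi]
            call_id = f"{g}|{fam}"
            member_seqs.setdefault(fam, {})[g] = seq
            manifest.families[fam].append(call_id)
            assignment[call_id] = f"{fam}{sub}"

    # --- plant fragmentation events ----------------------------------------
    def split_seq(seq: str) -> Tuple[str, str]:
        cut = int(len(seq) * rng.uniform(0.35, 0.65))
        return seq[:cut], seq[cut:]

    frag_targets: List[Tuple[str, str, str]] = []  # family, cause, genome
    end_genomes = list(rng.choice(genomes, size=config.n_end_split, replace=False))
    for i, fam in enumerate(frame_fams):
        frag_targets.append((fam, "frameshift_indel", genomes[int(rng.integers(config.n_genomes))]))
    for i, fam in enumerate(element_fams):
        frag_targets.append((fam, "element_insertion", genomes[int(rng.integers(config.n_genomes))]))
    for fam, g in zip(end_fams, end_genomes):
        frag_targets.append((fam, "end_split", g))

    fragmented: Dict[Tuple[str, str], Tuple[str, str, str]] = {}
    for fam, cause, g in frag_targets:
        n_seq, c_seq = split_seq(member_seqs[fam][g])
        n_id, c_id = f"{g}|{fam}.n", f"{g}|{fam}.c"
        fragmented[(fam, g)] = (n_id, c_id, cause)
        manifest.fragments.append(PlantedFragment(fam, g, n_id, c_id, cause, 1))
        del assignment[f"{g}|{fam}"]
        assignment[n_id] = fam
        assignment[c_id] = fam
        manifest.families[fam] = [
            x for x in manifest.families[fam] if x != f"{g}|{fam}"
        ] + [n_id, c_id]
        member_seqs[fam][f"__frag_n__{g}"] = n_seq
        member_seqs[fam][f"__frag_c__{g}"] = c_seq
        del member_seqs[fam][g]
        if cause == "element_insertion":
            el_len = int(rng.integers(100, 400))
            el_id = f"{g}|{fam}.el"
            el_seq = sampler.protein(el_len)
            assignment[el_id] = f"EL|{g}|{fam}"
            member_seqs.setdefault("__elements__", {})[el_id] = el_seq

        gap_small = int(rng.integers(3, 51))
        if cause == "frameshift_indel":
            unit = [(n_id, n_seq, 0), (c_id, c_seq, gap_small)]
            layout[g].append(unit)
        elif cause == "element_insertion":
            g1, g2 = int(rng.integers(20, 61)), int(rng.integers(20, 61))
            unit = [(n_id, n_seq, 0), (el_id, el_seq, g1), (c_id, c_seq, g2)]
            layout[g].append(unit)
        else:  # end_split: C-terminal piece opens the genome, N-terminal closes it
            pinned_start[g] = (c_id, c_seq)
            pinned_end[g] = (n_id, n_seq)

    # --- round-2 fragments: pieces split across a split family's clusters --
    for fam in split_fams[: config.n_round2_fragments]:
        g = genomes[0]  # a full-length member of subfamily "a"
        n_seq, c_seq = split_seq(member_seqs[fam][g])
        n_id, c_id = f"{g}|{fam}.n", f"{g}|{fam}.c"
        manifest.fragments.append(
            PlantedFragment(fam, g, n_id, c_id, "frameshift_indel", 2)
        )
        del assignment[f"{g}|{fam}"]
        assignment[n_id] = f"{fam}a"
        assignment[c_id] = f"{fam}b"
        manifest.families[fam] = [
            x for x in manifest.families[fam] if x != f"{g}|{fam}"
        ] + [n_id, c_id]
        member_seqs[fam][f"__frag_n__{g}"] = n_seq
        member_seqs[fam][f"__frag_c__{g}"] = c_seq
        del member_seqs[fam][g]
        gap_small = int(rng.integers(3, 51))
        layout[g].append([(n_id, n_seq, 0), (c_id, c_seq, gap_small)])
        fragmented[(fam, g)] = (n_id, c_id, "frameshift_indel")

    # --- paralog decoys -----------------------------------------------------
    for fam in decoy_fams:
        g = genomes[int(rng.integers(config.n_genomes))]
        d_id = f"{g}|{fam}.d2"
        d_seq = sampler.mutate(manifest.ancestors[fam], config.member_identity)
        assignment[d_id] = fam
        manifest.decoys.append((fam, g, d_id))
        manifest.families[fam].append(d_id)
        member_seqs[fam][f"__decoy__{g}"] = d_seq

    # --- fill layouts with the untouched calls ------------------------------
    for fam in families:
        for key, seq in member_seqs[fam].items():
            if key.startswith("__frag"):
                continue
            if key.startswith("__decoy__"):
                g = key[len("__decoy__"):]
                layout[g].append([(f"{g}|{fam}.d2", seq, 0)])
            else:
                g = key
                if (fam, g) in fragmented:
                    continue
                layout[g].append([(f"{g}|{fam}", seq, 0)])

    # --- assemble genome coordinates ----------------------------------------
    margin = 1500  # keeps interior genes clear of the 1 kb end margin
    for g in genomes:
        units = layout[g]
        order = rng.permutation(len(units))
        pos = 0
        calls_here: List[GeneCall] = []
        if g in pinned_start:
            cid, seq = pinned_start[g]
            start = int(rng.integers(10, 301))
            stop = start + _BP_PER_AA * len(seq)
            calls_here.append(GeneCall(cid, g, start, stop, "+", seq))
            pos = stop
        pos += margin
        for k in order:
            for cid, seq, gap in units[int(k)]:
                start = pos + (gap if gap else int(rng.integers(50, 301)))
                stop = start + _BP_PER_AA * len(seq)
                strand = "+" if (gap or cid.endswith((".n", ".c", ".el"))) else (
                    "+" if rng.random() < 0.5 else "-"
                )
                calls_here.append(GeneCall(cid, g, start, stop, strand, seq))
                pos = stop
        if g in pinned_end:
            cid, seq = pinned_end[g]
            start = pos + margin
            stop = start + _BP_PER_AA * len(seq)
            calls_here.append(GeneCall(cid, g, start, stop, "+", seq))
            length = stop + int(rng.integers(10, 301))
        else:
            length = pos + margin
        for c in calls_here:
            state.calls[c.id] = c
        state.genomes[g] = GenomeRecord(
            g, length, sorted((c.id for c in calls_here),
                              key=lambda i: (state.calls[i].start, i)),
        )

    for call_id, cid in assignment.items():
        state.clusters.setdefault(cid, set()).add(call_id)

    # --- expected SCG sets ---------------------------------------------------
    event_fams = set(frame_fams) | set(element_fams) | set(end_fams)
    r2_fams = set(split_fams[: config.n_round2_fragments])
    manifest.scg_before = sorted(
        fam for fam in families
        if fam not in split_set and fam not in event_fams and fam not in decoy_fams
    )
    manifest.scg_after = sorted(
        [fam for fam in families if fam not in split_set and fam not in decoy_fams]
        + [f"{fam}a" for fam in split_fams]  # merged id: smallest constituent
    )
    return state, manifest


# --------------------------------------------------------------------------
# on-disk fixture + truth scoring


def write_fixture(
    state: PangenomeState, manifest: TruthManifest, outdir: str | Path
) -> None:
    """Emit calls FASTA, coordinate and cluster tables, and the manifest
    (a fragments TSV plus a machine-readable JSON summary)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_gene_calls(state.calls, state.genomes, out / "calls.faa", out / "coords.tsv")
    pio.write_cluster_table(state.assignment(), state.calls, out / "clusters.tsv")
    pd.DataFrame(
        [asdict(f) for f in manifest.fragments],
        columns=["family", "genome", "n_id", "c_id", "cause", "round"],
    ).to_csv(out / "fragments.tsv", sep="\t", index=False)
    payload = {
        "families": manifest.families,
        "fragments": [asdict(f) for f in manifest.fragments],
        "split_families": manifest.split_families,
        "decoys": manifest.decoys,
        "scg_before": manifest.scg_before,
        "scg_after": manifest.scg_after,
    }
    (out / "manifest.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def score_against_truth(state: PangenomeState, manifest: TruthManifest) -> Dict[str, float]:
    """Compare corrected pipeline output with the planted ground truth."""
    from .scg import core_summary  # local import to avoid a cycle

    planted = {frozenset((f.n_id, f.c_id)): f for f in manifest.fragments}
    fused_pairs: Set[frozenset] = set()
    for call in state.calls.values():
        if call.is_fused:
            for a, b in zip(call.provenance, call.provenance[1:]):
                fused_pairs.add(frozenset((a, b)))
            if len(call.provenance) == 2:
                fused_pairs.add(frozenset(call.provenance))
    detected = [k for k in planted if k in fused_pairs]
    sensitivity = len(detected) / len(planted) if planted else 1.0
    precision = (
        sum(1 for k in fused_pairs if k in planted) / len(fused_pairs)
        if fused_pairs else 1.0
    )

    merged_ok = 0
    for fam, ca, cb in manifest.split_families:
        if state.merge_map.get(ca) == state.merge_map.get(cb) and state.merge_map.get(ca):
            merged_ok += 1
    split_recall = (
        merged_ok / len(manifest.split_families) if manifest.split_families else 1.0
    )

    decoy_ids = {d for _, _, d in manifest.decoys}
    decoy_fusions = sum(
        1 for call in state.calls.values() if call.is_fused
        and decoy_ids & set(call.provenance)
    )

    by_pair = {
        frozenset((r.call_a, r.call_b)): r.cause for r in state.fragclass_records
    }
    causes_ok = sum(
        1 for k in detected if by_pair.get(k) == planted[k].cause
    )
    # classification accuracy over the fused (hence classified) planted pairs
    fragclass_accuracy = causes_ok / len(detected) if detected else 1.0

    scg_now = sorted(core_summary(state).scg)
    return {
        "fragment_sensitivity": sensitivity,
        "fragment_precision": precision,
        "split_family_recall": split_recall,
        "decoy_fusions": float(decoy_fusions),
        "fragclass_accuracy": fragclass_accuracy,
        "scg_exact_match": float(scg_now == sorted(manifest.scg_after)),
        "n_scg_before_expected": float(len(manifest.scg_before)),
        "n_scg_after_expected": float(len(manifest.scg_after)),
        "n_scg_observed": float(len(scg_now)),
    }
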