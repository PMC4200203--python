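"""Two-assembler / two-sample consensus rule, deduplication and loci.

Assemblies from single cells are noisy; a spliced structure is kept only
when it is (a) detected by both assemblers in the same sample, or
(b) detected in at least two samples by the same assembler. Structures are
keyed by chromosome + intron chain; single-exon structures by their exon
interval with a configurable end slack (assemblers are imprecise about
transcript ends, exact junction identity is required for spliced forms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import networkx as nx

from .transcripts import (TranscriptModel, sort_transcripts, strands_compatible,
                          structure_key)

#: End slack (bases) when matching single-exon structures.
SINGLE_EXON_SLACK = 25


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def group_structures(transcripts: Sequence[TranscriptModel],
                     single_exon_slack: int = SINGLE_EXON_SLACK,
                     ) -> List[List[TranscriptModel]]:
    """Group records that represent the same spliced structure.

    Multi-exon: identical chromosome + intron chain. Single-exon: same
    chromosome, both ends within ``single_exon_slack`` bases (transitive
    closure). Groups are returned in deterministic genomic order.
    """
    multi: Dict[tuple, List[TranscriptModel]] = {}
    single: Dict[str, List[TranscriptModel]] = {}
    for t in transcripts:
        if t.n_exons >= 2:
            multi.setdefault(structure_key(t), []).append(t)
        else:
            single.setdefault(t.chrom, []).append(t)

    groups: List[List[TranscriptModel]] = []
    groups.extend(multi.values())

    for chrom in sorted(single):
        ts = sorted(single[chrom],
                    key=lambda t: (t.start, t.end, t.transcript_id))
        uf = _UnionFind(len(ts))
        for i, a in enumerate(ts):
            for j in range(i + 1, len(ts)):
                b = ts[j]
                if b.start - a.start > single_exon_slack:
                    break
                if abs(a.end - b.end) <= single_exon_slack:
                    uf.union(i, j)
        by_root: Dict[int, List[TranscriptModel]] = {}
        for i, t in enumerate(ts):
            by_root.setdefault(uf.find(i), []).append(t)
        groups.extend(by_root.values())

    for g in groups:
        g.sort(key=lambda t: t.transcript_id)
    groups.sort(key=lambda g: (g[0].chrom, min(t.start for t in g),
                               max(t.end for t in g), g[0].transcript_id))
    return groups


def merge_group(group: Sequence[TranscriptModel]) -> TranscriptModel:
    """Non-redundant representative of a structure group.

    Internal junctions are identical by construction; the representative
    takes the widest bounding terminal exons and the lexicographically
    smallest transcript id. Strand is the consensus of set strands (unknown
    if members disagree or none is set).
    """
    rep = min(group, key=lambda t: t.transcript_id)
    start = min(t.start for t in group)
    end = max(t.end for t in group)
    exons = list(rep.exons)
    exons[0] = (start, exons[0][1])
    exons[-1] = (exons[-1][0], end)
    strands = {t.strand for t in group} - {"."}
    strand = strands.pop() if len(strands) == 1 else "."
    return TranscriptModel(rep.transcript_id, rep.gene_id, rep.chrom, strand,
                           tuple(exons), biotype=rep.biotype)


def consensus_filter(sets_a: Mapping[str, Sequence[TranscriptModel]],
                     sets_b: Mapping[str, Sequence[TranscriptModel]],
                     single_exon_slack: int = SINGLE_EXON_SLACK,
                     ) -> List[TranscriptModel]:
    """Apply the consensus rule to per-sample sets of two assemblers.

    ``sets_a``/``sets_b`` map sample label → transcripts from assembler A/B.
    Returns the non-redundant union of retained structures (merged extents),
    in genomic order.
    """
    tagged: List[TranscriptModel] = []
    for assembler, sets in (("A", sets_a), ("B", sets_b)):
        for sample, ts in sets.items():
            for t in ts:
                tagged.append(TranscriptModel(
                    t.transcript_id, t.gene_id, t.chrom, t.strand, t.exons,
                    biotype=t.biotype, source=(assembler, sample)))

    retained: List[TranscriptModel] = []
    for group in group_structures(tagged, single_exon_slack):
        by_sample: Dict[str, set] = {}
        by_assembler: Dict[str, set] = {}
        for t in group:
            assembler, sample = t.source
            by_sample.setdefault(sample, set()).add(assembler)
            by_assembler.setdefault(assembler, set()).add(sample)
        both_in_one_sample = any(len(v) == 2 for v in by_sample.values())
        twice_same_assembler = any(len(v) >= 2 for v in by_assembler.values())
        if both_in_one_sample or twice_same_assembler:
            retained.append(merge_group(group))
    return sort_transcripts(retained)


def deduplicate(transcripts: Sequence[TranscriptModel],
                single_exon_slack: int = 0,
                ) -> List[TranscriptModel]:
    """Collapse records with identical structure to one record each."""
    return sort_transcripts(merge_group(g) for g in
                            group_structures(transcripts, single_exon_slack))


def assign_loci(transcripts: Sequence[TranscriptModel]) -> Dict[str, int]:
    """Group transcripts into loci.

    A locus is a connected component of the graph whose edges join
    transcripts sharing exonic bases on compatible strands (unknown strand
    overlaps both orientations). Returns transcript id → locus index
    (0-based, deterministic genomic order of the leftmost member).
    """
    ts = sort_transcripts(transcripts)
    g = nx.Graph()
    g.add_nodes_from(t.transcript_id for t in ts)
    by_chrom: Dict[str, List[TranscriptModel]] = {}
    for t in ts:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom_ts in by_chrom.values():
        for i, a in enumerate(chrom_ts):
            for b in chrom_ts[i + 1:]:
                if b.start >= a.end:
                    break
                if strands_compatible(a.strand, b.strand) and \
                        _share_exonic(a, b):
                    g.add_edge(a.transcript_id, b.transcript_id)
    order = {t.transcript_id: i for i, t in enumerate(ts)}
    comps = sorted(nx.connected_components(g),
                   key=lambda c: min(order[x] for x in c))
    return {tid: i for i, comp in enumerate(comps) for tid in comp}


def n_loci(transcripts: Sequence[TranscriptModel]) -> int:
    loci = assign_loci(transcripts)
    return len(set(loci.values())) if loci else 0


def _share_exonic(a: TranscriptModel, b: TranscriptModel) -> bool:
    for xa, xb in a.exons:
        for ya, yb in b.exons:
            if min(xb, yb) > max(xa, ya):
                return True
    return False
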