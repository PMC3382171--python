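"""Fusion-transcript detection from paired-end transcriptome reads.

A fusion transcript joins a 5' partner prefix (ending at base J5, 1-based)
to a 3' partner suffix (starting at base J3), so fragments straddling the
junction produce discordant ("chimeric") read pairs whose mates map to two
different reference transcripts.  The detection pipeline:

1. count chimeric pairs per unordered transcript pair;
2. collect the supporting reads (chimeric mates plus soft-clipped reads on
   the candidate partners) and assemble them into contigs with a de Bruijn
   graph;
3. localize the junction by splitting the contig at the point maximizing
   exact-match support in the two partners;
4. quantify expression with RBM (per-base reads x 1e6 / total library
   reads) and region folds, and translate the junction into a fusion ORF.

Coordinates are 1-based inclusive on the transcript sense strand; when the
junction sequence is shared by both partners the 5'-most split is reported
together with the homology interval over which it could slide.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .mapping import KmerReadMapper, ReadPairAlignment, TranscriptSet, revcomp

__all__ = [
    "ChimericPairTable",
    "FusionCall",
    "RBMProfile",
    "FusionORF",
    "AssemblyResult",
    "find_chimeric_pairs",
    "assemble_junction",
    "locate_junction",
    "compute_rbm",
    "region_fold",
    "fusion_orf",
    "FusionDetector",
    "InvalidParameterError",
]


class InvalidParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# chimeric pair counting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChimericPairTable:
    """Counts of read pairs whose mates map uniquely to two different transcripts.

    ``counts`` is ordered by descending support.  Pairs with an unmapped or
    ambiguous mate are excluded from counts but tallied in ``n_excluded``;
    concordant pairs (both mates on one transcript) in ``n_concordant``.
    """

    counts: tuple  # of ((tx_a, tx_b) sorted, count)
    n_excluded: int
    n_concordant: int

    def count(self, tx_a: str, tx_b: str) -> int:
        key = tuple(sorted((tx_a, tx_b)))
        for pair, n in self.counts:
            if pair == key:
                return n
        return 0


def find_chimeric_pairs(alignments: list[ReadPairAlignment]) -> ChimericPairTable:
    """Tally discordant transcript pairs from mapped read pairs."""
    tally: Counter = Counter()
    excluded = 0
    concordant = 0
    for pair in alignments:
        m1, m2 = pair.mate1, pair.mate2
        if m1.status != "unique" or m2.status != "unique":
            excluded += 1
            continue
        if m1.transcript == m2.transcript:
            concordant += 1
            continue
        tally[tuple(sorted((m1.transcript, m2.transcript)))] += 1
    ordered = tuple(sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])))
    return ChimericPairTable(counts=ordered, n_excluded=excluded, n_concordant=concordant)


# ---------------------------------------------------------------------------
# de novo junction assembly (de Bruijn unitigs)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssemblyResult:
    contigs: tuple  # sorted by length, longest first
    failed: bool  # no contig reached 2k


def assemble_junction(reads: list[str], k: int = 31) -> AssemblyResult:
    """Assemble reads (already in transcript orientation) into unitig contigs.

    Builds a k-mer de Bruijn graph and extracts maximal unambiguous paths.
    On error-free reads tiling a region the unitig reproduces the region
    exactly.  ``failed`` is set when no contig reaches 2k bases, which
    distinguishes assembly failure from a genuine absence of fusion evidence.
    """
    if len(reads) < 2:
        raise InvalidParameterError("assembly needs at least 2 reads")
    if k % 2 == 0 or k >= min(len(r) for r in reads):
        raise InvalidParameterError("k must be odd and smaller than the read length")
    kmers = set()
    for r in reads:
        for i in range(len(r) - k + 1):
            kmers.add(r[i : i + k])
    succ = defaultdict(list)
    pred = defaultdict(list)
    for km in kmers:
        succ[km[:-1]].append(km[-1])
        pred[km[1:]].append(km[0])

    def _is_linear(node: str) -> bool:
        return len(succ[node]) == 1 and len(pred[node]) == 1

    contigs = []
    visited = set()
    nodes = set(succ) | set(pred)
    # start unitigs at branch points / path starts
    for node in nodes:
        if _is_linear(node):
            continue
        for ch in succ[node]:
            km = node + ch
            if km in visited:
                continue
            path = [node, km[1:]]
            visited.add(km)
            cur = km[1:]
            while _is_linear(cur):
                nxt = cur + succ[cur][0]
                if nxt in visited:
                    break
                visited.add(nxt)
                cur = nxt[1:]
                path.append(cur)
            contigs.append(path[0] + "".join(p[-1] for p in path[1:]))
    # isolated cycles (all-linear components) — rare; walk any leftover k-mer
    for km in kmers:
        if km not in visited:
            visited.add(km)
            cur = km[1:]
            path = [km[:-1], cur]
            while _is_linear(cur):
                nxt = cur + succ[cur][0]
                if nxt in visited:
                    break
                visited.add(nxt)
                cur = nxt[1:]
                path.append(cur)
            contigs.append(path[0] + "".join(p[-1] for p in path[1:]))
    contigs.sort(key=lambda c: (-len(c), c))
    failed = not contigs or len(contigs[0]) < 2 * k
    return AssemblyResult(contigs=tuple(contigs), failed=failed)


# ---------------------------------------------------------------------------
# junction localization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FusionCall:
    """A localized fusion junction.

    The fusion sequence equals ``tx5[1..J5] + tx3[J3..len3]``; ``J5``/``J3``
    follow the 5'-most convention when junction bases are shared by both
    partners, with ``homology_interval`` giving how far the split can slide.
    """

    five_prime_tx: str
    j5: int
    three_prime_tx: str
    j3: int
    contig: str
    homology_interval: int
    supporting_pairs: int = 0
    spanning_reads: int = 0
    match5: int = 0  # exact-match bases supporting the 5' side of the split
    match3: int = 0
    contig_split: int = 0  # 0-based contig index of the first 3'-partner base


def _longest_suffix_in(contig: str, s: int, ref: str) -> int:
    """Longest t such that contig[s-t:s] occurs in ref (binary search; the
    predicate is monotone in t)."""
    lo, hi = 0, s
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if contig[s - mid : s] in ref:
            lo = mid
        else:
            hi = mid - 1
    return lo


def _longest_prefix_in(contig: str, s: int, ref: str) -> int:
    lo, hi = 0, len(contig) - s
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if contig[s : s + mid] in ref:
            lo = mid
        else:
            hi = mid - 1
    return lo


def locate_junction(
    contig: str,
    tx5: str,
    tx3: str,
    min_anchor: int = 25,
    five_prime_tx: str = "tx5",
    three_prime_tx: str = "tx3",
) -> FusionCall | None:
    """Split a contig between a 5' and a 3' partner transcript.

    Evaluates every split point s, scoring it by the longest exact match of
    the contig prefix (a suffix of contig[:s]) within ``tx5`` plus the
    longest exact match of the contig suffix (a prefix of contig[s:]) within
    ``tx3``; each side must anchor with at least ``min_anchor`` bases.
    Returns None when no split meets the anchors (e.g. the contig lies
    wholly within one transcript).
    """
    n = len(contig)
    if n < 2 * min_anchor:
        raise InvalidParameterError(
            f"contig length {n} is below 2 x min_anchor ({2 * min_anchor})"
        )
    best_score = -1
    best_splits: list[tuple[int, int, int]] = []
    for s in range(min_anchor, n - min_anchor + 1):
        m5 = _longest_suffix_in(contig, s, tx5)
        if m5 < min_anchor:
            continue
        m3 = _longest_prefix_in(contig, s, tx3)
        if m3 < min_anchor:
            continue
        score = m5 + m3
        if score > best_score:
            best_score = score
            best_splits = [(s, m5, m3)]
        elif score == best_score:
            best_splits.append((s, m5, m3))
    if not best_splits:
        return None
    s, m5, m3 = best_splits[0]  # 5'-most split
    homology = best_splits[-1][0] - s
    occ5 = tx5.find(contig[s - m5 : s])
    occ3 = tx3.find(contig[s : s + m3])
    return FusionCall(
        five_prime_tx=five_prime_tx,
        j5=occ5 + m5,  # 1-based coordinate of the last retained 5' base
        three_prime_tx=three_prime_tx,
        j3=occ3 + 1,  # 1-based coordinate of the first retained 3' base
        contig=contig,
        homology_interval=homology,
        match5=m5,
        match3=m3,
        contig_split=s,
    )


# ---------------------------------------------------------------------------
# coverage statistics (RBM)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RBMProfile:
    """Per-base coverage and RBM (reads per base per million library reads)."""

    transcript: str
    coverage: np.ndarray
    library_size: int

    @property
    def rbm(self) -> np.ndarray:
        return self.coverage * 1e6 / self.library_size


def compute_rbm(
    alignments: list[ReadPairAlignment],
    transcript: str,
    transcript_length: int,
    library_size: int,
) -> RBMProfile:
    """Per-base coverage of one transcript from all uniquely mapped mates.

    ``library_size`` is the total number of reads in the library (mapped or
    not), matching the "per million reads" normalization.
    """
    if library_size <= 0:
        raise InvalidParameterError("library_size must be positive")
    cov = np.zeros(transcript_length, dtype=float)
    for pair in alignments:
        for mate in (pair.mate1, pair.mate2):
            if mate.status == "unique" and mate.transcript == transcript:
                lo = mate.start - 1
                cov[lo : lo + mate.span] += 1
    return RBMProfile(transcript=transcript, coverage=cov, library_size=library_size)


def region_fold(
    profile_a: RBMProfile,
    profile_b: RBMProfile,
    region: tuple[int, int],
    pseudocount: float = 0.1,
) -> float:
    """Mean-RBM fold change of ``profile_a`` over ``profile_b`` in a region.

    ``region`` is 1-based inclusive; ``pseudocount`` (in RBM units)
    stabilizes folds over sparsely covered regions.
    """
    lo, hi = region
    if not (1 <= lo <= hi <= profile_a.coverage.size) or hi > profile_b.coverage.size:
        raise InvalidParameterError(f"region {region} out of transcript bounds")
    mean_a = float(profile_a.rbm[lo - 1 : hi].mean())
    mean_b = float(profile_b.rbm[lo - 1 : hi].mean())
    return (mean_a + pseudocount) / (mean_b + pseudocount)


# ---------------------------------------------------------------------------
# fusion ORF
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class FusionORF:
    """Amino-acid composition of a fusion transcript's reading frame."""

    in_frame: bool
    junction_in_utr: bool = False
    five_prime_aa: tuple[int, int] | None = None  # 1-based inclusive
    three_prime_aa: tuple[int, int] | None = None
    protein_length: int | None = None


def _orf_length(seq: str, cds_start: int) -> int:
    """Residues encoded from cds_start (1-based) to the first stop codon."""
    n_aa = 0
    for i in range(cds_start - 1, len(seq) - 2, 3):
        if seq[i : i + 3] in _STOPS:
            break
        n_aa += 1
    return n_aa


def fusion_orf(
    call: FusionCall,
    cds_start5: int,
    cds_start3: int,
    seq3: str,
) -> FusionORF:
    """Translate junction coordinates into fused protein ranges.

    The junction is in frame when the retained 5' coding bases form whole
    codons, (J5 - cds_start5 + 1) % 3 == 0, and the 3' partner resumes on a
    codon boundary of its own frame, (J3 - cds_start3) % 3 == 0.  The 3'
    range runs to the annotated stop of the 3' partner's ORF.
    """
    if call.j5 < cds_start5:
        return FusionORF(in_frame=False, junction_in_utr=True)
    in_frame = (call.j5 - cds_start5 + 1) % 3 == 0 and (call.j3 - cds_start3) % 3 == 0
    if not in_frame:
        return FusionORF(in_frame=False)
    aa5_end = (call.j5 - cds_start5 + 1) // 3
    aa3_start = (call.j3 - cds_start3) // 3 + 1
    aa3_end = _orf_length(seq3, cds_start3)
    return FusionORF(
        in_frame=True,
        five_prime_aa=(1, aa5_end),
        three_prime_aa=(aa3_start, aa3_end),
        protein_length=aa5_end + (aa3_end - aa3_start + 1),
    )


# ---------------------------------------------------------------------------
# end-to-end detector
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FusionReport:
    call: FusionCall | None
    chimeric: ChimericPairTable
    assembly: AssemblyResult | None
    status: str  # "called" | "no_fusion" | "assembly_failed" | "no_junction"


class FusionDetector:
    """Pipeline: map pairs -> chimeric table -> assemble -> localize junction.

    Parameters follow the individual stages; ``min_support`` is the minimum
    chimeric-pair count before a candidate is pursued, ``min_clip`` the
    soft-clip length that flags a read as potentially junction-spanning.
    """

    def __init__(
        self,
        seed_length: int = 20,
        max_mismatch_rate: float = 0.04,
        k: int = 31,
        min_anchor: int = 25,
        min_support: int = 2,
        min_clip: int = 10,
        spanning_flank: int = 20,
    ):
        self.seed_length = seed_length
        self.max_mismatch_rate = max_mismatch_rate
        self.k = k
        self.min_anchor = min_anchor
        self.min_support = min_support
        self.min_clip = min_clip
        self.spanning_flank = spanning_flank

    def detect(self, pairs, transcripts: TranscriptSet) -> FusionReport:
        """Run the full pipeline on (pair_id, seq1, seq2) read pairs."""
        mapper = KmerReadMapper(self.seed_length, self.max_mismatch_rate).fit(transcripts)
        alignments = mapper.map_pairs(pairs)
        return self.detect_from_alignments(alignments, transcripts)

    def detect_from_alignments(
        self, alignments: list[ReadPairAlignment], transcripts: TranscriptSet
    ) -> FusionReport:
        table = find_chimeric_pairs(alignments)
        if not table.counts or table.counts[0][1] < self.min_support:
            return FusionReport(None, table, None, "no_fusion")
        (tx_a, tx_b), support = table.counts[0]
        reads = self._collect_evidence(alignments, tx_a, tx_b)
        assembly = assemble_junction(reads, k=self.k)
        if assembly.failed:
            return FusionReport(None, table, assembly, "assembly_failed")
        seq_a = transcripts.sequence(tx_a)
        seq_b = transcripts.sequence(tx_b)
        best = None
        for contig in assembly.contigs[:3]:
            for cseq in (contig, revcomp(contig)):
                for (t5, s5, t3, s3) in ((tx_a, seq_a, tx_b, seq_b), (tx_b, seq_b, tx_a, seq_a)):
                    if len(cseq) < 2 * self.min_anchor:
                        continue
                    call = locate_junction(
                        cseq, s5, s3, min_anchor=self.min_anchor,
                        five_prime_tx=t5, three_prime_tx=t3,
                    )
                    if call is None:
                        continue
                    if best is None or call.match5 + call.match3 > best.match5 + best.match3:
                        best = call
        if best is None:
            return FusionReport(None, table, assembly, "no_junction")
        spanning = self._count_spanning(reads, best)
        call = FusionCall(
            five_prime_tx=best.five_prime_tx, j5=best.j5,
            three_prime_tx=best.three_prime_tx, j3=best.j3,
            contig=best.contig, homology_interval=best.homology_interval,
            supporting_pairs=support, spanning_reads=spanning,
            match5=best.match5, match3=best.match3, contig_split=best.contig_split,
        )
        return FusionReport(call, table, assembly, "called")

    def _collect_evidence(self, alignments, tx_a: str, tx_b: str) -> list[str]:
        reads = []
        targets = {tx_a, tx_b}
        for pair in alignments:
            m1, m2 = pair.mate1, pair.mate2
            chimeric = (
                m1.status == "unique" and m2.status == "unique"
                and {m1.transcript, m2.transcript} == targets
            )
            for mate in (m1, m2):
                clipped = (
                    mate.status == "unique" and mate.transcript in targets
                    and max(mate.clip5, mate.clip3) >= self.min_clip
                )
                if (chimeric or clipped) and mate.oriented_seq:
                    reads.append(mate.oriented_seq)
        return reads

    def _count_spanning(self, reads: list[str], call: FusionCall) -> int:
        split = call.contig_split
        f = self.spanning_flank
        lo, hi = max(0, split - f), min(len(call.contig), split + f)
        window = call.contig[lo:hi]
        return sum(1 for r in reads if window in r)
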