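"""Toy-scale transcriptome read mapping: exact k-mer seeds, ungapped extension.

Reads are placed on a reference transcript set by looking up exact seed
k-mers in an index, extending the hit without gaps, and soft-clipping any
unmatched prefix/suffix.  A read straddling a fusion junction therefore maps
to the partner contributing the larger share of its bases, with the other
share soft-clipped — the signal later used to collect junction evidence.
Only reads with a unique best placement count as mapped; ties between
transcripts are recorded as ambiguous.  Reverse-strand hits are reported in
transcript (sense) orientation with 1-based inclusive coordinates.

This deliberately replaces a production aligner at fixture scale; externally
aligned reads can be supplied instead through the minimal-SAM reader.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TranscriptSet",
    "MateAlignment",
    "ReadPairAlignment",
    "KmerReadMapper",
    "revcomp",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    pass


_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class TranscriptSet:
    """A reference transcript set with optional CDS start annotations (1-based)."""

    records: tuple  # of (transcript_id, sequence)
    cds_start: dict | None = None

    def __post_init__(self):
        ids = [tid for tid, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("transcript ids must be unique")
        for tid, seq in self.records:
            if set(seq) - set("ACGTN"):
                raise ConfigurationError(f"transcript {tid} has non-ACGTN characters")
            if self.cds_start and tid in self.cds_start:
                if not (1 <= self.cds_start[tid] <= len(seq)):
                    raise ConfigurationError(f"cds_start out of range for {tid}")

    def sequence(self, tid: str) -> str:
        for t, seq in self.records:
            if t == tid:
                return seq
        raise KeyError(tid)

    @property
    def ids(self) -> list[str]:
        return [tid for tid, _ in self.records]


@dataclass(frozen=True)
class MateAlignment:
    """One mate's placement, in transcript orientation.

    ``status`` is "unique", "unmapped" or "ambiguous"; coordinates are only
    meaningful for unique placements.  ``span + clip5 + clip3 == read length``.
    """

    status: str
    transcript: str | None = None
    start: int = 0  # 1-based first matched base on the transcript
    strand: str = "+"
    span: int = 0  # matched bases (including tolerated mismatches)
    clip5: int = 0  # soft-clipped bases before the match, transcript orientation
    clip3: int = 0
    mismatches: int = 0
    oriented_seq: str | None = None  # read sequence in transcript orientation


@dataclass(frozen=True)
class ReadPairAlignment:
    pair_id: str
    mate1: MateAlignment
    mate2: MateAlignment


_UNMAPPED = MateAlignment(status="unmapped")


class KmerReadMapper:
    """Exact-seeded ungapped read mapper over a small transcript set.

    Parameters
    ----------
    seed_length : int
        Exact-match seed size (default 20).
    max_mismatch_rate : float
        Mismatch budget per matched span (default 0.04).
    """

    def __init__(self, seed_length: int = 20, max_mismatch_rate: float = 0.04):
        self.seed_length = seed_length
        self.max_mismatch_rate = max_mismatch_rate

    def fit(self, transcripts: TranscriptSet):
        """Index every k-mer position of every transcript."""
        if len(transcripts.records) == 0:
            raise ConfigurationError("transcript set is empty")
        k = self.seed_length
        index: dict[str, list] = {}
        seqs = {}
        for ti, (tid, seq) in enumerate(transcripts.records):
            seqs[tid] = seq
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append((ti, pos))
        self.index_ = index
        self.transcripts_ = transcripts
        self._seqs = seqs
        return self

    # -- single-read placement ------------------------------------------------

    def _extend(self, read: str, tseq: str, diag: int, seed_off: int):
        """Ungapped extension around a seed at read offset ``seed_off``.

        ``diag`` is the transcript position (0-based) aligned with read[0].
        Returns (tstart0, span, clip5, clip3, mismatches) or None.
        """
        n = len(read)
        # fast path: full-length exact match
        if 0 <= diag and diag + n <= len(tseq) and tseq[diag : diag + n] == read:
            return diag, n, 0, 0, 0
        budget = int(self.max_mismatch_rate * n)
        k = self.seed_length
        mism = 0

        def _ahead_matches(i: int, step: int) -> bool:
            # absorb a mismatch only when the next 3 bases keep matching,
            # so extension cannot creep across a fusion junction by chance
            for d in (1, 2, 3):
                j = i + step * d
                if j < 0 or j >= n or diag + j < 0 or diag + j >= len(tseq):
                    return False
                if read[j] != tseq[diag + j]:
                    return False
            return True

        # extend left of the seed; mismatch tails are trimmed (left tracks the
        # outermost matching base)
        left = seed_off
        i = seed_off - 1
        while i >= 0 and diag + i >= 0:
            if read[i] == tseq[diag + i]:
                left = i
            else:
                if mism >= budget or not _ahead_matches(i, -1):
                    break
                mism += 1
            i -= 1
        # extend right of the seed
        right = seed_off + k  # exclusive
        i = right
        while i < n and diag + i < len(tseq):
            if read[i] == tseq[diag + i]:
                right = i + 1
            else:
                if mism >= budget or not _ahead_matches(i, +1):
                    break
                mism += 1
            i += 1
        span = right - left
        # recount mismatches inside the kept window only
        mism = sum(1 for j in range(left, right) if read[j] != tseq[diag + j])
        if span < k or mism > int(self.max_mismatch_rate * span):
            return None
        return diag + left, span, left, n - right, mism

    def map_read(self, read: str) -> MateAlignment:
        """Place one read; returns a unique best placement or unmapped/ambiguous."""
        k = self.seed_length
        if len(read) < k:
            return _UNMAPPED
        candidates = {}
        for strand, seq in (("+", read), ("-", revcomp(read))):
            n = len(seq)
            offsets = sorted({0, (n - k) // 2, n - k})
            for off in offsets:
                for ti, pos in self.index_.get(seq[off : off + k], ()):
                    tid = self.transcripts_.records[ti][0]
                    key_diag = pos - off
                    ext = self._extend(seq, self._seqs[tid], key_diag, off)
                    if ext is None:
                        continue
                    tstart0, span, clip5, clip3, mism = ext
                    key = (tid, tstart0, strand)
                    cand = MateAlignment(
                        status="unique", transcript=tid, start=tstart0 + 1,
                        strand=strand, span=span, clip5=clip5, clip3=clip3,
                        mismatches=mism, oriented_seq=seq,
                    )
                    prev = candidates.get(key)
                    if prev is None or (span, -mism) > (prev.span, -prev.mismatches):
                        candidates[key] = cand
        if not candidates:
            return _UNMAPPED
        ranked = sorted(candidates.values(), key=lambda a: (-a.span, a.mismatches))
        best = ranked[0]
        if len(ranked) > 1:
            runner = ranked[1]
            if (runner.span, runner.mismatches) == (best.span, best.mismatches) and (
                runner.transcript != best.transcript
            ):
                return MateAlignment(status="ambiguous")
        return best

    def map_pairs(self, pairs) -> list[ReadPairAlignment]:
        """Map an iterable of (pair_id, seq1, seq2) read pairs."""
        out = []
        for pair_id, s1, s2 in pairs:
            out.append(ReadPairAlignment(pair_id, self.map_read(s1), self.map_read(s2)))
        return out
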