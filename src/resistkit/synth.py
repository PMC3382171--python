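"""Synthetic-data generators with recorded ground truth.

Every pipeline stage has a matching generator that emulates the structure of
the study data it is tested against: sigmoidal viability plates with
lognormal count noise, Bliss-additive / rescue-synergy / antagonistic
combination matrices, a fusion transcriptome (a 3522-base 5' partner cut at
base 2006 joined to a 2947-base 3' partner resuming at base 1202,
over-expressed up to ~20-fold), 75-base paired-end reads with a 250+-30
fragment size, and piecewise-constant CNV probe tracks with a 4-fold
(log2 = 2) amplified segment.  Generators are deterministic under a fixed
seed and return a :class:`SimTruth` record sufficient to recompute every
expected value downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cnv import ProbeTrack
from .doseresponse import DoseLadder, FourPLFit, PlateReadout, four_pl
from .mapping import TranscriptSet, revcomp

__all__ = [
    "SimTruth",
    "simulate_plate",
    "simulate_combination",
    "make_transcript",
    "make_coding_transcript",
    "make_fusion_transcript",
    "simulate_read_pairs",
    "simulate_cnv_track",
    "fusion_study_transcriptome",
    "fusion_abundance_for_region_fold",
    "expected_chimeric_pairs",
    "ConfigurationError",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimTruth:
    """Generator parameters plus per-item records, JSON round-trippable."""

    params: dict = field(default_factory=dict)
    records: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        return json.dumps({"params": self.params, "records": self.records},
                          default=_default, indent=None)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(params=d["params"], records=d["records"])


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# viability plates
# ---------------------------------------------------------------------------


def simulate_plate(
    params: FourPLFit,
    ladder: DoseLadder,
    noise_cv: float = 0.05,
    baseline_mean: float = 50_000.0,
    untreated_mean: float = 400_000.0,
    replicates: int = 3,
    seed: int | None = None,
    drug: str = "drug",
) -> tuple[PlateReadout, SimTruth]:
    """Simulate raw luminescence counts for one dose-response experiment.

    Treated counts follow baseline + (untreated - baseline) * (1 - TGI(dose)),
    each well multiplied by lognormal noise of the given CV; ``noise_cv = 0``
    yields deterministic counts so the TGI round trip is exact.  Defaults
    emulate a 3-day CellTiter-Glo readout (~8x growth over baseline).
    """
    if not untreated_mean > baseline_mean > 0:
        raise ConfigurationError(
            f"need untreated_mean > baseline_mean > 0, got {untreated_mean}, {baseline_mean}"
        )
    rng = np.random.default_rng(seed)
    doses = ladder.concentrations
    tgi = four_pl(doses, params.lower, params.upper, params.ic50, params.hill)
    span = untreated_mean - baseline_mean
    wells = []
    for i, (dose, t) in enumerate(zip(doses, tgi)):
        expected = baseline_mean + span * (1.0 - t)
        for r in range(replicates):
            count = expected * _lognormal_factor(rng, noise_cv, None)
            wells.append((f"T{i}_{r}", drug, float(dose), float(count)))
    baseline_wells = tuple(
        (f"B{r}", float(baseline_mean * _lognormal_factor(rng, noise_cv, None)))
        for r in range(replicates)
    )
    untreated_wells = tuple(
        (f"U{r}", float(untreated_mean * _lognormal_factor(rng, noise_cv, None)))
        for r in range(replicates)
    )
    plate = PlateReadout(tuple(wells), baseline_wells, untreated_wells)
    truth = SimTruth(
        params={
            "lower": params.lower, "upper": params.upper, "ic50": params.ic50,
            "hill": params.hill, "noise_cv": noise_cv, "seed": seed,
            "baseline_mean": baseline_mean, "untreated_mean": untreated_mean,
            "replicates": replicates, "ladder": {
                "top": ladder.top, "fold": ladder.fold, "n_points": ladder.n_points,
            },
        },
        records={"tgi": tgi.tolist()},
    )
    return plate, truth


# ---------------------------------------------------------------------------
# combination matrices
# ---------------------------------------------------------------------------


def simulate_combination(
    params_a: FourPLFit,
    params_b: FourPLFit,
    model: str,
    ladder_a: DoseLadder,
    ladder_b: DoseLadder,
    rescue_params: FourPLFit | None = None,
    noise_cv: float = 0.0,
    gate_a: float = 0.0,
    gate_b: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, SimTruth]:
    """Simulate an observed TGI matrix over a dose grid with zero-dose edges.

    ``model``: "bliss" (observed equals the Bliss expectation of the two
    single-agent curves), "rescue" (single agents act per their own curves —
    typically flat — while combination cells with both doses above the gates
    follow ``rescue_params`` evaluated on drug A's dose; emulates a resistant
    clone killed only by the combination), or "antagonism"
    (observed = 0.8 * max(A, B), below Bliss wherever both agents act).

    Returns (observed, doses_a, doses_b, truth); dose axes ascend and start
    at zero.
    """
    if model not in ("bliss", "rescue", "antagonism"):
        raise ConfigurationError(f"unknown combination model {model!r}")
    if model == "rescue" and rescue_params is None:
        raise ConfigurationError("rescue model requires rescue_params")
    rng = np.random.default_rng(seed)
    da = np.concatenate([[0.0], np.sort(ladder_a.concentrations)])
    db = np.concatenate([[0.0], np.sort(ladder_b.concentrations)])

    def _single(params, doses):
        out = np.zeros_like(doses)
        nz = doses > 0
        out[nz] = four_pl(doses[nz], params.lower, params.upper, params.ic50, params.hill)
        return np.clip(out, 0.0, 1.0)

    A = _single(params_a, da)
    B = _single(params_b, db)
    bliss = A[:, None] + B[None, :] - A[:, None] * B[None, :]
    if model == "bliss":
        obs = bliss.copy()
    elif model == "antagonism":
        obs = 0.8 * np.maximum(A[:, None], B[None, :])
    else:  # rescue
        obs = bliss.copy()
        rescued = (da[:, None] > max(gate_a, 0.0)) & (db[None, :] > max(gate_b, 0.0))
        rescue_tgi = np.where(
            da > 0,
            four_pl(np.where(da > 0, da, 1.0), rescue_params.lower,
                    rescue_params.upper, rescue_params.ic50, rescue_params.hill),
            0.0,
        )
        obs = np.where(rescued, rescue_tgi[:, None], obs)
    obs_noisy = obs * _lognormal_factor(rng, noise_cv, obs.shape)
    truth = SimTruth(
        params={"model": model, "noise_cv": noise_cv, "seed": seed,
                "gate_a": gate_a, "gate_b": gate_b},
        records={"observed_clean": obs.tolist(), "single_a": A.tolist(),
                 "single_b": B.tolist()},
    )
    return obs_noisy, da, db, truth


# ---------------------------------------------------------------------------
# transcripts and fusions
# ---------------------------------------------------------------------------


def make_transcript(length: int, gc: float = 0.5, seed=None) -> str:
    """Random transcript sequence; deterministic per seed."""
    if length < 1:
        raise ConfigurationError(f"transcript length must be >= 1, got {length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def make_coding_transcript(
    n_codons: int, utr5: int = 60, utr3: int = 100, gc: float = 0.5, seed=None
) -> tuple[str, int]:
    """Random transcript with a clean ORF: returns (sequence, cds_start).

    The ORF encodes ``n_codons`` sense codons (ATG first, no internal stops)
    followed by a stop codon; ``cds_start`` is 1-based.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = make_transcript(3, gc=gc, seed=rng)
        if c not in _STOPS:
            codons.append(c)
    seq = (
        make_transcript(utr5, gc=gc, seed=rng)
        + "".join(codons)
        + "TAA"
        + make_transcript(utr3, gc=gc, seed=rng)
    )
    return seq, utr5 + 1


def make_fusion_transcript(tx5: str, j5: int, tx3: str, j3: int) -> str:
    """Join prefix(tx5, J5) to suffix(tx3, J3); coordinates 1-based inclusive."""
    if not (1 <= j5 <= len(tx5)):
        raise ConfigurationError(f"J5={j5} out of range 1..{len(tx5)}")
    if not (1 <= j3 <= len(tx3)):
        raise ConfigurationError(f"J3={j3} out of range 1..{len(tx3)}")
    return tx5[:j5] + tx3[j3 - 1 :]


def _mutate_to_differ(seq: str, idx: int, avoid: str, rng: np.random.Generator) -> str:
    """Ensure seq[idx] differs from ``avoid``; mutate deterministically if not."""
    if seq[idx] != avoid:
        return seq
    options = [b for b in "ACGT" if b != avoid]
    return seq[:idx] + options[int(rng.integers(len(options)))] + seq[idx + 1 :]


def fusion_study_transcriptome(
    seed: int | None = 0,
    len5: int = 3522,
    len3: int = 2947,
    j5: int = 2006,
    j3: int = 1202,
    n_background: int = 0,
    background_length: int = 2000,
) -> dict:
    """Build the study's fusion transcriptome: wild-type partners plus fusion.

    Generates a 5' partner of ``len5`` bases and a 3' partner of ``len3``
    bases, then a fusion of prefix(tx5, j5) + suffix(tx3, j3).  Bases
    flanking the junction are adjusted (at most two substitutions) so the
    junction carries zero micro-homology and the reported split cannot
    slide.  Optionally adds a pool of unrelated background transcripts that
    emulates the remainder of the transcriptome, so the fusion can be a
    small mass fraction of a library as it would be in real data.

    Returns a dict with keys tx5, tx3, fusion (sequences), j5, j3,
    background (list of (id, seq)), and a ready :class:`TranscriptSet` of
    the wild-type reference ("wt_set").
    """
    rng = np.random.default_rng(seed)
    tx5 = make_transcript(len5, seed=rng)
    tx3 = make_transcript(len3, seed=rng)
    # zero junction homology: the base after the retained prefix must differ
    # from the first retained 3' base's predecessor context, in both directions
    if j5 < len5:
        tx5 = _mutate_to_differ(tx5, j5, tx3[j3 - 1], rng)  # right slide blocked
    if j3 >= 2:
        tx3 = _mutate_to_differ(tx3, j3 - 2, tx5[j5 - 1], rng)  # left slide blocked
    fusion = make_fusion_transcript(tx5, j5, tx3, j3)
    background = [
        (f"bg{i}", make_transcript(background_length, seed=rng))
        for i in range(n_background)
    ]
    wt_records = [("tx5", tx5), ("tx3", tx3)] + background
    return {
        "tx5": tx5,
        "tx3": tx3,
        "fusion": fusion,
        "j5": j5,
        "j3": j3,
        "background": background,
        "wt_set": TranscriptSet(records=tuple(wt_records)),
    }


# ---------------------------------------------------------------------------
# paired-end reads
# ---------------------------------------------------------------------------


def _effective_length(length: int, insert_mean: float) -> float:
    return max(length - insert_mean + 1.0, 1.0)


def simulate_read_pairs(
    transcripts: dict[str, str],
    abundances: dict[str, float],
    n_pairs: int,
    read_len: int = 75,
    insert_mean: float = 250.0,
    insert_sd: float = 30.0,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[list[tuple[str, str, str]], SimTruth]:
    """Simulate paired-end reads from a weighted transcript pool.

    Fragments are drawn per transcript with probability proportional to
    molar abundance x effective length (length - insert_mean + 1); the two
    mates are read from the fragment ends on opposite strands.  Inserts are
    Gaussian, clamped into [read_len, transcript length] (fragments shorter
    than a read would run into adapter; fragments longer than the transcript
    are resampled by the clamp).  ``error_rate`` > 0 adds uniform
    substitutions for stress testing only.

    Returns (pairs, truth): pairs are (pair_id, seq1, seq2); the truth
    records every fragment's transcript, 0-based start and insert size.
    """
    if n_pairs < 0:
        raise ConfigurationError("n_pairs must be >= 0")
    ids = [t for t in transcripts if abundances.get(t, 0.0) > 0]
    if not ids:
        raise ConfigurationError("no transcript has positive abundance")
    for tid in ids:
        if len(transcripts[tid]) < read_len:
            raise ConfigurationError(f"transcript {tid} shorter than read length")
    rng = np.random.default_rng(seed)
    weights = np.array(
        [abundances[t] * _effective_length(len(transcripts[t]), insert_mean) for t in ids]
    )
    counts = rng.multinomial(n_pairs, weights / weights.sum())
    pairs: list[tuple[str, str, str]] = []
    frag_records: dict[str, list] = {}
    for tid, n in zip(ids, counts):
        seq = transcripts[tid]
        L = len(seq)
        inserts = np.clip(
            np.rint(rng.normal(insert_mean, insert_sd, size=n)).astype(int), read_len, L
        )
        starts = np.floor(rng.random(n) * (L - inserts + 1)).astype(int)
        recs = []
        for i, (s, ins) in enumerate(zip(starts, inserts)):
            r1 = seq[s : s + read_len]
            r2 = revcomp(seq[s + ins - read_len : s + ins])
            if error_rate > 0:
                r1 = _add_errors(r1, error_rate, rng)
                r2 = _add_errors(r2, error_rate, rng)
            pairs.append((f"{tid}:{i}", r1, r2))
            recs.append((int(s), int(ins)))
        frag_records[tid] = recs
    truth = SimTruth(
        params={
            "n_pairs": n_pairs, "read_len": read_len, "insert_mean": insert_mean,
            "insert_sd": insert_sd, "error_rate": error_rate, "seed": seed,
            "abundances": dict(abundances),
        },
        records={"fragments": frag_records},
    )
    return pairs, truth


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    out = list(read)
    hits = np.flatnonzero(rng.random(len(read)) < rate)
    for i in hits:
        out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def expected_chimeric_pairs(
    truth: SimTruth, fusion_id: str, junction_split: int, read_len: int = 75
) -> int:
    """Oracle: fusion fragments whose mates sit (by base majority) on opposite
    junction sides, hence map as a discordant pair against the wild-type set.

    ``junction_split`` is the number of 5'-partner bases in the fusion (= J5).
    """
    n = 0
    half = read_len / 2.0
    for start, insert in truth.records["fragments"].get(fusion_id, []):
        m1_prefix = min(max(junction_split - start, 0), read_len)
        m2_start = start + insert - read_len
        m2_prefix = min(max(junction_split - m2_start, 0), read_len)
        if m1_prefix > half and m2_prefix < half:
            n += 1
    return n


def fusion_abundance_for_region_fold(
    target_fold: float,
    background_weight: float,
    len5: int = 3522,
    len3: int = 2947,
    fusion_len: int = 3752,
    insert_mean: float = 250.0,
    a5: float = 1.0,
    a3: float = 1.0,
) -> float:
    """Fusion molar abundance giving an expected 3'-region RBM fold.

    Per-base expected coverage of a transcript is proportional to its molar
    abundance divided by the library's total abundance x effective-length
    weight, so with a parental weight W the resistant/parental fold over the
    3'-partner suffix is (a3 + f) * W / (a3 * (W + f * eff_fusion)).  Solving
    for f requires W > target_fold * a3 * eff_fusion: the background pool
    must dominate the library, as the rest of a transcriptome does in a real
    RNA-seq library.
    """
    eff5 = _effective_length(len5, insert_mean)
    eff3 = _effective_length(len3, insert_mean)
    eff_f = _effective_length(fusion_len, insert_mean)
    W = background_weight + a5 * eff5 + a3 * eff3
    denom = W - target_fold * a3 * eff_f
    if denom <= 0:
        raise ConfigurationError(
            "background pool too small for the requested fold; increase background_weight"
        )
    return a3 * W * (target_fold - 1.0) / denom


def rbm_study_abundances(
    study: dict,
    target_fold: float = 20.0,
    background_abundance: float = 10.0,
    insert_mean: float = 250.0,
) -> tuple[dict, dict, dict]:
    """Molar abundances for the resistant-vs-parental coverage comparison.

    Given a :func:`fusion_study_transcriptome` with a background pool,
    returns (transcripts, parental_abundances, resistant_abundances) where
    both wild-type partners have unit abundance, background transcripts
    carry ``background_abundance`` each, and the resistant library adds the
    fusion at the molar abundance that makes the expected 3'-suffix RBM fold
    equal ``target_fold``.
    """
    transcripts = {"tx5": study["tx5"], "tx3": study["tx3"]}
    parental = {"tx5": 1.0, "tx3": 1.0}
    bw = 0.0
    for tid, seq in study["background"]:
        transcripts[tid] = seq
        parental[tid] = background_abundance
        bw += background_abundance * _effective_length(len(seq), insert_mean)
    f = fusion_abundance_for_region_fold(
        target_fold, bw,
        len5=len(study["tx5"]), len3=len(study["tx3"]),
        fusion_len=len(study["fusion"]), insert_mean=insert_mean,
    )
    resistant = dict(parental)
    transcripts_res = dict(transcripts)
    transcripts_res["fusion"] = study["fusion"]
    resistant["fusion"] = f
    return transcripts_res, parental, resistant


# ---------------------------------------------------------------------------
# CNV probe tracks
# ---------------------------------------------------------------------------


def simulate_cnv_track(
    segment_truth: list[tuple[int, float]],
    noise_sd: float = 0.25,
    seed: int | None = None,
    chrom: str = "chr7",
    start_pos: int = 1,
    spacing: int = 1,
) -> tuple[ProbeTrack, SimTruth]:
    """Simulate a probe track from (n_probes, mean_log2) segments plus noise."""
    if len(segment_truth) < 1:
        raise ConfigurationError("need at least one segment")
    rng = np.random.default_rng(seed)
    means = np.concatenate(
        [np.full(int(n), float(m)) for n, m in segment_truth]
    )
    noise = rng.normal(0.0, noise_sd, size=means.size) if noise_sd > 0 else 0.0
    values = means + noise
    pos = start_pos + spacing * np.arange(means.size)
    track = ProbeTrack(
        chrom=np.full(means.size, chrom), pos=pos.astype(float), log2_ratio=values
    )
    bounds = np.cumsum([0] + [int(n) for n, _ in segment_truth])
    truth = SimTruth(
        params={"noise_sd": noise_sd, "seed": seed, "chrom": chrom,
                "spacing": spacing, "start_pos": start_pos},
        records={"segments": [[int(n), float(m)] for n, m in segment_truth],
                 "boundaries": bounds.tolist()},
    )
    return track, truth
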