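"""Raw paired-end reads to translated full-length VNAR proteins.

The stage order mirrors a standard amplicon protocol: quality/adapter
trimming, FLASH-style overlap merging of the mate pair, filtering on the
conserved nucleotide anchors flanking the VNAR insert, and in-frame
translation with an internal-stop filter. Counts surviving each stage are
tallied in a :class:`QcReport`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
from Bio.Seq import Seq
from numba import njit

from .config import PipelineConfig

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadPair:
    """One forward/reverse mate pair; qualities are Phred+33 strings."""

    id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: str
    rev_qual: str

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class Amplicon:
    """Merged consensus of a mate pair."""

    id: str
    seq: str
    overlap_len: int
    overlap_mismatches: int


@dataclass
class MergeFailure:
    id: str
    reason: str


@dataclass
class TranslatedVnar:
    """A full-length in-frame VNAR protein and its source nucleotides."""

    id: str
    protein: str
    nt_insert: str


@dataclass
class TranslationReject:
    id: str
    reason: str  # frame | ambiguous | internal_stop | length


@dataclass
class FlankNotFound:
    reason: str  # flank5 | flank3


@dataclass
class QcReport:
    """Per-stage survivor counts; monotone non-increasing by construction."""

    n_pairs_in: int = 0
    n_merged: int = 0
    n_flank_pass: int = 0
    n_in_frame: int = 0
    n_no_stop: int = 0
    n_len_pass: int = 0

    def as_dict(self) -> dict:
        return {
            "n_pairs_in": self.n_pairs_in,
            "n_merged": self.n_merged,
            "n_flank_pass": self.n_flank_pass,
            "n_in_frame": self.n_in_frame,
            "n_no_stop": self.n_no_stop,
            "n_len_pass": self.n_len_pass,
        }


# ---------------------------------------------------------------------------
# quality / adapter trimming
# ---------------------------------------------------------------------------

_TRIM_WINDOW = 4


def _trim_one(seq: str, qual: str, min_phred: int) -> int:
    """Return the kept length after 3' sliding-window trimming.

    From the 3' end, bases are dropped while the terminal base is below
    ``min_phred`` or the mean Phred of the trailing window (length 4,
    shorter near the 5' end) is. Monotone: never lengthens a read.
    """
    n = len(seq)
    if n == 0:
        return 0
    # fast path: every base already passes
    if min(qual) >= chr(min_phred + 33):
        return n
    phred = [ord(c) - 33 for c in qual]
    while n > 0:
        window = phred[max(0, n - _TRIM_WINDOW):n]
        if phred[n - 1] >= min_phred and sum(window) / len(window) >= min_phred:
            break
        n -= 1
    return n


def _strip_adapter(seq: str, qual: str, adapter: str) -> Tuple[str, str]:
    """Truncate at the leftmost adapter occurrence (<=1 mismatch).

    A partial adapter running off the 3' end also matches when at least
    5 bases of its prefix align with <=1 mismatch.
    """
    la = len(adapter)
    if la == 0:
        return seq, qual
    min_tail = min(5, la)
    for start in range(0, len(seq) - min_tail + 1):
        span = min(la, len(seq) - start)
        mism = sum(1 for i in range(span) if seq[start + i] != adapter[i])
        if mism <= 1:
            return seq[:start], qual[:start]
    return seq, qual


def quality_trim(pair: ReadPair, min_phred: int, adapter: Optional[str] = None) -> ReadPair:
    """Adapter- and quality-trim both mates; never lengthens a read."""
    if min_phred < 0:
        raise ValueError("min_phred must be >= 0")
    fs, fq = pair.fwd_seq, pair.fwd_qual
    rs, rq = pair.rev_seq, pair.rev_qual
    if adapter:
        fs, fq = _strip_adapter(fs, fq, adapter)
        rs, rq = _strip_adapter(rs, rq, adapter)
    nf = _trim_one(fs, fq, min_phred)
    nr = _trim_one(rs, rq, min_phred)
    return ReadPair(pair.id, fs[:nf], rs[:nr], fq[:nf], rq[:nr])


# ---------------------------------------------------------------------------
# pair merging
# ---------------------------------------------------------------------------

@njit(cache=False)
def _best_overlap(f: np.ndarray, r: np.ndarray, min_overlap: int, max_frac: float):
    """Scan candidate overlap lengths between fwd suffix and rev-comp prefix.

    Admissible overlaps have mismatch fraction <= max_frac. Among them the
    minimal mismatch fraction wins; ties go to the shortest overlap (the
    longest merged product). Comparisons use exact integer cross products
    so float rounding cannot reorder candidates. Returns (-1, -1) when no
    overlap qualifies.
    """
    lmax = min(f.size, r.size)
    best_l = -1
    best_m = 0
    for L in range(min_overlap, lmax + 1):
        allowed = int(max_frac * L + 1e-9)
        if best_l > 0:
            # strict improvement requires m/L < best_m/best_l
            cap_beat = (best_m * L - 1) // best_l
            if cap_beat < allowed:
                allowed = cap_beat
        if allowed < 0:
            continue
        off = f.size - L
        m = 0
        ok = True
        for i in range(L):
            if f[off + i] != r[i]:
                m += 1
                if m > allowed:
                    ok = False
                    break
        if ok:
            best_l = L
            best_m = m
            if m == 0:
                break  # ties go to shorter overlaps: unbeatable
    return best_l, best_m


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def merge_pair(pair: ReadPair, min_overlap_nt: int,
               max_overlap_mismatch_frac: float) -> Amplicon | MergeFailure:
    """FLASH-style merge of a mate pair into a consensus amplicon.

    The reverse mate is reverse-complemented, the best admissible overlap
    (see :func:`_best_overlap`) is chosen, and disagreeing overlap bases are
    resolved in favor of the higher-quality base (forward wins ties).
    """
    if not pair.fwd_seq or not pair.rev_seq:
        return MergeFailure(pair.id, "empty_read")
    rc_seq = revcomp(pair.rev_seq)
    rc_qual = pair.rev_qual[::-1]
    best_l, best_m = _best_overlap(
        _encode(pair.fwd_seq), _encode(rc_seq),
        min_overlap_nt, max_overlap_mismatch_frac,
    )
    if best_l < 0:
        return MergeFailure(pair.id, "no_qualifying_overlap")
    off = len(pair.fwd_seq) - best_l
    if best_m == 0:
        consensus = pair.fwd_seq[off:]
    else:
        chars = []
        for i in range(best_l):
            a, b = pair.fwd_seq[off + i], rc_seq[i]
            if a == b or pair.fwd_qual[off + i] >= rc_qual[i]:
                chars.append(a)
            else:
                chars.append(b)
        consensus = "".join(chars)
    merged = pair.fwd_seq[:off] + consensus + rc_seq[best_l:]
    return Amplicon(pair.id, merged, best_l, best_m)


# ---------------------------------------------------------------------------
# flank location
# ---------------------------------------------------------------------------

def _find_approx(seq: str, motif: str, max_mm: int, start: int = 0) -> int:
    """Leftmost-best approximate occurrence of motif in seq[start:], or -1.

    Positions are scanned left to right; the position minimizing the Hamming
    mismatch count (subject to <= max_mm) wins, earlier positions breaking
    ties.
    """
    if max_mm == 0:
        return seq.find(motif, start)
    best_pos, best_mm = -1, max_mm + 1
    lm = len(motif)
    for pos in range(start, len(seq) - lm + 1):
        mm = 0
        for i in range(lm):
            if seq[pos + i] != motif[i]:
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_pos, best_mm = pos, mm
            if mm == 0:
                break
    return best_pos


def locate_flanks(seq: str, flank5: str, flank3: str,
                  max_mismatches: int = 0) -> Tuple[int, int] | FlankNotFound:
    """Locate the insert interval (0-based, half-open) between the anchors.

    Both the sequence and its reverse complement are searched; orientation
    is normalized so that ``flank5`` lies upstream. With an empty ``flank3``
    the insert extends from the end of ``flank5`` to the end of the
    sequence. Returns the interval in the *normalized* orientation along
    with nothing else; callers needing the normalized sequence should use
    :func:`extract_insert`.
    """
    res = _locate_oriented(seq, flank5, flank3, max_mismatches)
    if isinstance(res, FlankNotFound):
        res_rc = _locate_oriented(revcomp(seq), flank5, flank3, max_mismatches)
        if not isinstance(res_rc, FlankNotFound):
            return res_rc
    return res


def _locate_oriented(seq: str, flank5: str, flank3: str, max_mm: int):
    if not flank5:
        raise ValueError("flank5 must be non-empty")
    p5 = _find_approx(seq, flank5, max_mm)
    if p5 < 0:
        return FlankNotFound("flank5")
    start = p5 + len(flank5)
    if not flank3:
        return (start, len(seq))
    p3 = _find_approx(seq, flank3, max_mm, start=start)
    if p3 < 0:
        return FlankNotFound("flank3")
    return (start, p3)


def extract_insert(seq: str, flank5: str, flank3: str,
                   max_mismatches: int = 0) -> str | FlankNotFound:
    """Insert nucleotides between the anchors, orientation-normalized."""
    res = _locate_oriented(seq, flank5, flank3, max_mismatches)
    if not isinstance(res, FlankNotFound):
        return seq[res[0]:res[1]]
    rc = revcomp(seq)
    res = _locate_oriented(rc, flank5, flank3, max_mismatches)
    if not isinstance(res, FlankNotFound):
        return rc[res[0]:res[1]]
    return res


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def translate_insert(nt_insert: str, record_id: str = "",
                     min_protein_len_aa: int = 1,
                     max_protein_len_aa: int = 10**9) -> TranslatedVnar | TranslationReject:
    """Standard-genetic-code translation of an insert, frame fixed at 0.

    Rejection reasons: ``frame`` (length not a codon multiple), ``ambiguous``
    (a codon contains N), ``internal_stop`` (a stop before the final codon),
    ``length`` (protein outside configured bounds). A stop codon in the
    final position is stripped rather than rejected.
    """
    if len(nt_insert) % 3 != 0 or len(nt_insert) == 0:
        return TranslationReject(record_id, "frame")
    if "N" in nt_insert:
        return TranslationReject(record_id, "ambiguous")
    protein = str(Seq(nt_insert).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
        nt_insert = nt_insert[:-3]
    if "*" in protein:
        return TranslationReject(record_id, "internal_stop")
    if not min_protein_len_aa <= len(protein) <= max_protein_len_aa:
        return TranslationReject(record_id, "length")
    return TranslatedVnar(record_id, protein, nt_insert)


# ---------------------------------------------------------------------------
# full stage pipeline
# ---------------------------------------------------------------------------

def process_pairs(pairs: Iterable[ReadPair],
                  config: PipelineConfig) -> Tuple[List[TranslatedVnar], QcReport]:
    """Run trim -> merge -> flank filter -> translate over a pair stream."""
    qc = QcReport()
    out: List[TranslatedVnar] = []
    for pair in pairs:
        qc.n_pairs_in += 1
        pair = quality_trim(pair, config.min_phred)
        merged = merge_pair(pair, config.min_overlap_nt, config.max_overlap_mismatch_frac)
        if isinstance(merged, MergeFailure):
            continue
        qc.n_merged += 1
        insert = extract_insert(merged.seq, config.flank5, config.flank3,
                                config.max_flank_mismatches)
        if isinstance(insert, FlankNotFound):
            continue
        qc.n_flank_pass += 1
        if len(insert) % 3 != 0 or len(insert) == 0 or "N" in insert:
            continue
        qc.n_in_frame += 1
        result = translate_insert(insert, merged.id,
                                  config.min_protein_len_aa, config.max_protein_len_aa)
        if isinstance(result, TranslationReject):
            if result.reason == "length":
                qc.n_no_stop += 1
            continue
        qc.n_no_stop += 1
        qc.n_len_pass += 1
        out.append(result)
    return out, qc


def process_library(path_fwd, path_rev,
                    config: PipelineConfig) -> Tuple[List[TranslatedVnar], QcReport]:
    """Process a FASTQ mate-pair file couple into translated VNAR proteins."""
    from .io import read_fastq_pair

    return process_pairs(read_fastq_pair(path_fwd, path_rev), config)
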