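"""Bipartite sigma-factor promoter motifs: discovery, construction, scanning.

Sigma-factor promoters carry two conserved boxes, the -35 and -10 elements,
separated by a variable spacer (16-19 bp here).  The workflow mirrors how such
motifs are derived from ChIP-seq data:

1. extract 100 bp windows centered on peak summits,
2. discover the -10 half-site with a ZOOPS (zero-or-one occurrence per
   sequence) EM motif finder on both strands,
3. extract 10 bp segments starting 23 bp upstream of the -10 sites and
   discover the -35 half-site in them,
4. join the two half-sites into composite motifs, one per spacer length,
   with the spacer columns held at background frequencies,
5. scan sequences with all spacer variants on both strands, assigning each
   occurrence an exact p-value (probability, under the 0-order background
   model, that a random word scores at least as high), and keep hits with
   p below a threshold (0.05 by default).

Scores are log-odds in bits against the background model, discretized on a
fixed lattice; p-values come from a dynamic program convolving the per-column
score distributions, so they are exact for the discretized motif.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParameterError, StructuralError

ALPHABET = "ACGT"
DEFAULT_PSEUDOCOUNT = 0.25
DEFAULT_GRANULARITY_BITS = 0.01
DEFAULT_P_THRESHOLD = 0.05
SPACER_RANGE = (16, 19)

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_COMPLEMENT_IDX = np.array([3, 2, 1, 0, 4], dtype=np.int8)
_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


def gc_background(gc: float) -> np.ndarray:
    """0-order background with the given GC content (A/T and C/G split evenly)."""
    if not (0 < gc < 1):
        raise ParameterError("gc must be in (0, 1)")
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def estimate_background(seqs: Iterable[str]) -> np.ndarray:
    """0-order base frequencies of a sequence set (one pseudo-observation each)."""
    counts = np.ones(4)
    for s in seqs:
        e = encode(s)
        counts += np.bincount(e[e < 4], minlength=4)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakRegion:
    """A called peak: 0-based half-open interval with an absolute summit."""

    contig: str
    start: int
    end: int
    summit: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise StructuralError(
                f"peak {self.name or self.contig}: summit {self.summit} outside "
                f"[{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class PWM:
    """Per-position base-probability matrix over A, C, G, T."""

    probs: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: np.ndarray = field(default_factory=uniform_background)
    name: str = "motif"

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise StructuralError("probs must be a width x 4 matrix")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise StructuralError("each PWM row must sum to 1")
        if np.any(probs < 0):
            raise StructuralError("PWM entries must be non-negative")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=1))

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """Per-column log2(p / background); requires strictly positive entries."""
        bg = self.background if background is None else np.asarray(background, float)
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / bg)

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits relative to the background."""
        lo = self.log_odds()
        return np.where(self.probs > 0, self.probs * lo, 0.0).sum(axis=1)

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1], self.pseudocount, self.background,
                   name=self.name + "_rc")


@dataclass(frozen=True)
class CompositeMotif:
    """A -35 and a -10 half-site joined across an explicit spacer.

    Spacer columns sit at background frequencies, so they contribute exactly
    zero to every log-odds score; the total width is
    ``pwm35.width + spacer + pwm10.width``.
    """

    pwm35: PWM
    pwm10: PWM
    spacer: int
    spacer_range: tuple[int, int] = SPACER_RANGE

    def __post_init__(self) -> None:
        lo, hi = self.spacer_range
        if not (lo <= self.spacer <= hi):
            raise ParameterError(f"spacer {self.spacer} outside [{lo}, {hi}]")

    @property
    def width(self) -> int:
        return self.pwm35.width + self.spacer + self.pwm10.width

    @property
    def informative_columns(self) -> np.ndarray:
        w35 = self.pwm35.width
        return np.concatenate(
            [np.arange(w35), w35 + self.spacer + np.arange(self.pwm10.width)]
        )

    def probs(self, background: np.ndarray) -> np.ndarray:
        """Full-width probability matrix with background spacer columns."""
        rows = np.tile(np.asarray(background, float), (self.width, 1))
        rows[: self.pwm35.width] = self.pwm35.probs
        rows[self.pwm35.width + self.spacer:] = self.pwm10.probs
        return rows


def build_composite_motif(
    pwm35: PWM, pwm10: PWM, spacer: int,
    spacer_range: tuple[int, int] = SPACER_RANGE,
) -> CompositeMotif:
    return CompositeMotif(pwm35, pwm10, spacer, spacer_range)


@dataclass(frozen=True)
class MotifHit:
    """One scored motif occurrence.

    ``offset`` is the 0-based start of the occupied window on the forward
    strand; ``matched`` is the motif-oriented word (reverse-complemented for
    minus-strand hits); ``spacer`` is None for plain (non-composite) motifs.
    """

    seq_id: str
    offset: int
    strand: str
    score: float
    p_value: float
    spacer: int | None = None
    matched: str = ""

    @property
    def width(self) -> int:
        return len(self.matched)


# ---------------------------------------------------------------------------
# Peak windows
# ---------------------------------------------------------------------------

def extract_peak_windows(
    peaks: Sequence[PeakRegion],
    genome: Mapping[str, str],
    width: int = 100,
    policy: str = "skip",
) -> dict[str, str]:
    """Extract ``width`` bp windows centered on peak summits, uppercased.

    The window is ``[summit - width//2, summit + width//2)``.  Windows
    overrunning a contig end are skipped with a warning (``policy='skip'``),
    clamped (``'clip'``), or raise (``'error'``).
    """
    if policy not in ("skip", "clip", "error"):
        raise ParameterError(f"unknown policy {policy!r}")
    out: dict[str, str] = {}
    for i, peak in enumerate(peaks):
        if peak.contig not in genome:
            raise StructuralError(f"contig {peak.contig!r} not in genome")
        contig = genome[peak.contig]
        s = peak.summit - width // 2
        e = s + width
        if s < 0 or e > len(contig):
            if policy == "error":
                raise StructuralError(
                    f"peak {peak.name or i}: window [{s}, {e}) overruns contig"
                )
            if policy == "skip":
                warnings.warn(
                    f"peak {peak.name or i}: window overruns contig; skipped",
                    stacklevel=2,
                )
                continue
            s, e = max(s, 0), min(e, len(contig))
        name = peak.name or f"peak_{i}"
        if name in out:
            name = f"{name}_{i}"
        out[name] = contig[s:e].upper()
    return out


# ---------------------------------------------------------------------------
# PWM construction
# ---------------------------------------------------------------------------

def build_pwm(
    sites: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
    name: str = "motif",
) -> PWM:
    """Estimate a PWM from aligned, equal-length ACGT sites.

    Column probabilities are ``(count + pseudocount * background) /
    (n + pseudocount)``.
    """
    if len(sites) < 2:
        raise StructuralError("need at least two sites")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise StructuralError("sites must have equal length")
    if pseudocount < 0:
        raise ParameterError("pseudocount must be non-negative")
    bg = uniform_background() if background is None else np.asarray(background, float)
    counts = np.zeros((width, 4))
    for s in sites:
        e = encode(s)
        if np.any(e == 4):
            raise StructuralError(f"non-ACGT base in site {s!r}")
        counts[np.arange(width), e] += 1
    probs = (counts + pseudocount * bg) / (len(sites) + pseudocount)
    return PWM(probs, pseudocount, bg, name=name)


def consensus_pwm(
    consensus: str,
    strength: float = 0.85,
    background: np.ndarray | None = None,
    name: str = "motif",
) -> PWM:
    """PWM putting ``strength`` on the consensus base, the rest on the others
    in proportion to the background.  Handy for constructing synthetic motifs."""
    if not (0 < strength < 1):
        raise ParameterError("strength must be in (0, 1)")
    bg = uniform_background() if background is None else np.asarray(background, float)
    e = encode(consensus)
    if np.any(e == 4):
        raise ParameterError("consensus must be ACGT only")
    probs = np.zeros((len(consensus), 4))
    for i, b in enumerate(e):
        others = np.delete(np.arange(4), b)
        rest = bg[others] / bg[others].sum()
        probs[i, b] = strength
        probs[i, others] = (1 - strength) * rest
    return PWM(probs, 0.0, bg, name=name)


# ---------------------------------------------------------------------------
# ZOOPS-EM motif discovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZoopsResult:
    pwm: PWM
    #: per sequence: (offset, strand, site probability) of the best placement
    sites: dict[str, tuple[int, str, float]]
    gamma: float
    log_likelihood: float
    ll_trace: np.ndarray
    #: log-likelihood gain over the pure-background (no-motif) model; how much
    #: evidence the sequence set carries for the motif's presence
    ll_gain: float = 0.0


def _zoops_init(enc_seqs, width, bg, rng) -> np.ndarray:
    """Seed a PWM from one random word, heavily smoothed toward background."""
    candidates = [e for e in enc_seqs if len(e) >= width]
    e = candidates[rng.integers(len(candidates))]
    j = int(rng.integers(len(e) - width + 1))
    word = e[j:j + width]
    probs = np.tile(bg * 0.4, (width, 1))
    for c, b in enumerate(word):
        if b < 4:
            probs[c, b] += 0.6
    return probs / probs.sum(axis=1, keepdims=True)


def discover_motif_zoops(
    seqs: Mapping[str, str],
    width: int,
    revcomp_scan: bool = True,
    n_starts: int = 5,
    seed: int = 0,
    max_iter: int = 80,
    tol: float = 1e-6,
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ZoopsResult:
    """EM motif discovery under the ZOOPS model (zero or one site/sequence).

    Each sequence contains a site with probability ``gamma`` at a uniformly
    chosen placement (both strands when ``revcomp_scan``); expectation-
    maximization alternates placement posteriors with weighted-count PWM and
    ``gamma`` updates.  The best of ``n_starts`` random initializations by
    final log-likelihood is returned; deterministic given ``seed``.
    """
    ids = list(seqs)
    if not ids:
        raise ParameterError("no sequences")
    if width < 1 or width > min(len(seqs[i]) for i in ids):
        raise ParameterError("width out of range for the sequence set")
    bg = estimate_background(seqs.values()) if background is None else np.asarray(background, float)
    enc_seqs = [encode(seqs[i]) for i in ids]
    cenc_seqs = [_COMPLEMENT_IDX[e] for e in enc_seqs]
    log_bg5 = np.append(np.log(bg), 0.0)

    best: tuple | None = None
    for start in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), start]))
        probs = _zoops_init(enc_seqs, width, bg, rng)
        gamma = 0.5
        ll_trace: list[float] = []
        prev_ll = -np.inf
        for _ in range(max_iter):
            lut = np.zeros((width, 5))
            lut[:, :4] = np.log(np.maximum(probs, 1e-12)) - np.log(bg)
            stats_counts = pseudocount * np.tile(bg, (width, 1))
            gamma_num = 0.0
            ll = 0.0
            placements: list[tuple] = []
            for e, ce in zip(enc_seqs, cenc_seqs):
                n_pos = len(e) - width + 1
                logr_f = np.zeros(n_pos)
                for c in range(width):
                    logr_f += lut[c][e[c:c + n_pos]]
                if revcomp_scan:
                    logr_r = np.zeros(n_pos)
                    for c in range(width):
                        logr_r += lut[c][ce[width - 1 - c:width - 1 - c + n_pos]]
                    logr = np.concatenate([logr_f, logr_r])
                else:
                    logr = logr_f
                m = len(logr)
                shift = max(float(np.max(logr)), 0.0)
                site_terms = (gamma / m) * np.exp(logr - shift)
                none_term = (1.0 - gamma) * np.exp(-shift)
                inner = none_term + site_terms.sum()
                ll += float(log_bg5[e].sum()) + shift + np.log(inner)
                r = site_terms / inner  # posterior per placement
                p_site = float(r.sum())
                gamma_num += p_site
                rf = r[:n_pos]
                for c in range(width):
                    np.add.at(stats_counts[c], e[c:c + n_pos], rf)
                if revcomp_scan:
                    rr = r[n_pos:]
                    for c in range(width):
                        np.add.at(
                            stats_counts[c],
                            ce[width - 1 - c:width - 1 - c + n_pos], rr,
                        )
                jbest = int(np.argmax(r)) if m else 0
                if jbest < n_pos:
                    placements.append((jbest, "+", p_site))
                else:
                    placements.append((jbest - n_pos, "-", p_site))
            ll_trace.append(ll)
            probs = stats_counts[:, :4]
            probs = probs / probs.sum(axis=1, keepdims=True)
            gamma = min(max(gamma_num / len(enc_seqs), 1e-4), 1 - 1e-4)
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                break
            prev_ll = ll
        if best is None or ll_trace[-1] > best[0]:
            best = (ll_trace[-1], probs, gamma, placements, np.array(ll_trace))

    ll_final, probs, gamma, placements, trace = best
    pwm = PWM(probs, pseudocount, bg, name=f"zoops_w{width}")
    sites = {sid: plc for sid, plc in zip(ids, placements)}
    log_p0_total = float(sum(log_bg5[e].sum() for e in enc_seqs))
    return ZoopsResult(pwm, sites, gamma, ll_final, trace,
                       ll_gain=ll_final - log_p0_total)


def extract_upstream_segments(
    seqs: Mapping[str, str],
    sites: Mapping[str, tuple[int, str]],
    site_width: int,
    offset: int = 23,
    length: int = 10,
) -> dict[str, str]:
    """Segments of ``length`` bp starting ``offset`` bp upstream of each site.

    For a plus-strand site starting at ``s`` the segment is
    ``[s - offset, s - offset + length)``; minus-strand sites are handled by
    the coordinate mirror (the computation runs on the reverse complement).
    Sequences whose segment would overrun are skipped with a warning.
    """
    out: dict[str, str] = {}
    for sid, (pos, strand) in sites.items():
        seq = seqs[sid]
        if strand == "-":
            seq = revcomp(seq)
            pos = len(seq) - site_width - pos
        s = pos - offset
        if s < 0 or s + length > len(seq):
            warnings.warn(f"{sid}: upstream segment out of range; skipped",
                          stacklevel=2)
            continue
        out[sid] = seq[s:s + length].upper()
    return out


# ---------------------------------------------------------------------------
# Exact p-values by score-distribution dynamic programming
# ---------------------------------------------------------------------------

def _int_score_matrix(motif, background: np.ndarray, granularity: float) -> np.ndarray:
    """Width x 5 integer log-odds matrix on the score lattice.

    Entries are round(log2(p/bg) / granularity); spacer columns of a composite
    and the unknown-base column (index 4) are zero, so both contribute nothing
    to any score (background substitution).
    """
    if granularity <= 0:
        raise ParameterError("granularity must be positive")
    if isinstance(motif, CompositeMotif):
        probs = motif.probs(background)
    else:
        probs = motif.probs
    probs = np.maximum(probs, 1e-9)
    probs = probs / probs.sum(axis=1, keepdims=True)
    lo = np.log2(probs / background)
    S = np.zeros((probs.shape[0], 5), dtype=np.int64)
    S[:, :4] = np.round(lo / granularity).astype(np.int64)
    if isinstance(motif, CompositeMotif):
        spacer_rows = np.setdiff1d(np.arange(motif.width), motif.informative_columns)
        S[spacer_rows] = 0
    return S


@dataclass(frozen=True)
class ScorePValueTable:
    """Exact mapping from lattice scores to tail probabilities.

    ``tail[i]`` is P(score >= min_score + i) under the background model; it is
    monotone non-increasing and ``tail[0] == 1``.
    """

    granularity: float
    min_score: int
    tail: np.ndarray

    def pvalue_int(self, score):
        idx = np.clip(np.asarray(score) - self.min_score, 0, len(self.tail) - 1)
        return self.tail[idx]

    def pvalue_bits(self, score_bits: float) -> float:
        return float(self.pvalue_int(int(round(score_bits / self.granularity))))

    def threshold_int(self, p: float) -> int:
        """Smallest lattice score whose tail probability is <= p."""
        idx = int(np.searchsorted(-self.tail, -p, side="left"))
        return self.min_score + idx


def score_pvalue_table(
    motif,
    background: np.ndarray | None = None,
    granularity: float = DEFAULT_GRANULARITY_BITS,
) -> ScorePValueTable:
    """Exact score distribution of a PWM or composite motif under background.

    Dynamic programming convolves the per-column discretized score
    distributions: after column c the array holds P(partial score = s) for
    every reachable lattice score s.  The resulting p-values are exact for the
    discretized motif (discretization error <= width * granularity / 2 bits).
    """
    bg = uniform_background() if background is None else np.asarray(background, float)
    S = _int_score_matrix(motif, bg, granularity)[:, :4]
    dist = np.array([1.0])
    cur_lo = 0
    for row in S:
        lo, hi = int(row.min()), int(row.max())
        new = np.zeros(len(dist) + hi - lo)
        for b in range(4):
            off = int(row[b]) - lo
            new[off:off + len(dist)] += bg[b] * dist
        dist = new
        cur_lo += lo
    tail = np.minimum(np.cumsum(dist[::-1])[::-1], 1.0)
    return ScorePValueTable(granularity, cur_lo, tail)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _scan_one_motif(
    motif, seqs: Mapping[str, str], bg: np.ndarray, granularity: float,
    p_threshold: float, warned: set,
) -> list[MotifHit]:
    S = _int_score_matrix(motif, bg, granularity)
    table = score_pvalue_table(motif, bg, granularity)
    width = S.shape[0]
    S_rev = S[::-1][:, _COMPLEMENT_IDX]
    spacer = motif.spacer if isinstance(motif, CompositeMotif) else None
    if isinstance(motif, CompositeMotif):
        cols = motif.informative_columns
    else:
        cols = np.arange(width)
    hits: list[MotifHit] = []
    for sid, seq in seqs.items():
        e = encode(seq)
        if len(e) < width:
            continue
        if np.any(e == 4) and sid not in warned:
            warnings.warn(
                f"{sid}: non-ACGT bases scored as background", stacklevel=3
            )
            warned.add(sid)
        n_pos = len(e) - width + 1
        for strand, mat in (("+", S), ("-", S_rev)):
            scores = np.zeros(n_pos, dtype=np.int64)
            for c in cols if strand == "+" else (width - 1 - cols):
                scores += mat[c][e[c:c + n_pos]]
            pvals = table.pvalue_int(scores)
            for j in np.nonzero(pvals <= p_threshold)[0]:
                word = seq[j:j + width].upper()
                hits.append(
                    MotifHit(
                        seq_id=sid,
                        offset=int(j),
                        strand=strand,
                        score=float(scores[j] * granularity),
                        p_value=float(pvals[j]),
                        spacer=spacer,
                        matched=word if strand == "+" else revcomp(word),
                    )
                )
    return hits


def _hit_rank(h: MotifHit) -> tuple:
    # min p first; ties: leftmost, then + strand, then shortest spacer
    return (h.p_value, h.offset, 0 if h.strand == "+" else 1, h.spacer or 0)


def dedupe_overlapping(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Keep the best (lowest-p) hit per cluster of overlapping windows on each
    sequence; spacer variants of the same site collapse to the best one."""
    out: list[MotifHit] = []
    by_seq: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append(h)
    for sid in sorted(by_seq):
        seq_hits = sorted(by_seq[sid], key=lambda h: (h.offset, h.offset + h.width))
        cluster: list[MotifHit] = []
        cluster_end = -1
        for h in seq_hits:
            if cluster and h.offset >= cluster_end:
                out.append(min(cluster, key=_hit_rank))
                cluster = []
                cluster_end = -1
            cluster.append(h)
            cluster_end = max(cluster_end, h.offset + h.width)
        if cluster:
            out.append(min(cluster, key=_hit_rank))
    return out


def scan_sequences(
    motifs,
    seqs: Mapping[str, str],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    background: np.ndarray | None = None,
    granularity: float = DEFAULT_GRANULARITY_BITS,
    dedupe: bool = True,
) -> list[MotifHit]:
    """Scan sequences with one or more motifs on both strands.

    Every offset is scored against every motif (composite spacer variants
    included); occurrences with exact p-value <= ``p_threshold`` are returned.
    The background defaults to the 0-order frequencies of the scanned set.
    With ``dedupe``, overlapping hits on a sequence collapse to the lowest-p
    one, so each site is reported once with its best spacer.
    """
    if not (0 < p_threshold <= 1):
        raise ParameterError("p_threshold must be in (0, 1]")
    if isinstance(motifs, (PWM, CompositeMotif)):
        motifs = [motifs]
    bg = estimate_background(seqs.values()) if background is None else np.asarray(background, float)
    warned: set = set()
    hits: list[MotifHit] = []
    for motif in motifs:
        hits.extend(_scan_one_motif(motif, seqs, bg, granularity, p_threshold, warned))
    if dedupe:
        hits = dedupe_overlapping(hits)
    return sorted(hits, key=lambda h: (h.seq_id, h.offset, h.strand, h.spacer or 0))


# ---------------------------------------------------------------------------
# Hit filtering and tallies
# ---------------------------------------------------------------------------

def matches_pattern(word: str, pattern: str) -> bool:
    """Case-insensitive match where '-' in the pattern is a wildcard."""
    if len(word) != len(pattern):
        return False
    return all(p == "-" or w == p.upper() for w, p in zip(word.upper(), pattern))


def filter_best_and_pattern(
    hits: Sequence[MotifHit],
    pattern: str = "--TA---T--",
) -> list[MotifHit]:
    """Union of (i) the lowest-p hit on each sequence and (ii) all hits whose
    matched core equals ``pattern`` ('-' denotes any base).

    Ties on minimum p break to the leftmost hit, then the + strand.  All hits
    must have cores of the pattern's length; the output is order-independent.
    """
    if any(len(h.matched) != len(pattern) for h in hits):
        raise ParameterError("pattern length does not match the motif core width")
    by_seq: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append(h)
    kept: dict[tuple, MotifHit] = {}
    for sid, seq_hits in by_seq.items():
        best = min(seq_hits, key=_hit_rank)
        kept[(best.seq_id, best.offset, best.strand, best.spacer)] = best
    for h in hits:
        if matches_pattern(h.matched, pattern):
            kept[(h.seq_id, h.offset, h.strand, h.spacer)] = h
    return sorted(kept.values(), key=lambda h: (h.seq_id, h.offset, h.strand))


def tally_spacers(
    hits: Sequence[MotifHit],
    spacer_range: tuple[int, int] = SPACER_RANGE,
) -> dict[int, int]:
    """Count retained hits by spacer length over the configured range."""
    tally = {s: 0 for s in range(spacer_range[0], spacer_range[1] + 1)}
    for h in hits:
        if h.spacer is None:
            continue
        tally[h.spacer] = tally.get(h.spacer, 0) + 1
    return tally


# ---------------------------------------------------------------------------
# File formats: FASTA, narrowPeak/BED, minimal MEME motif text
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_narrowpeak(path) -> list[PeakRegion]:
    """MACS2 narrowPeak (10 columns; the 10th is the summit offset from start)
    or plain BED (summit defaults to the interval midpoint)."""
    peaks = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for i, row in df.iterrows():
        contig, start, end = str(row[0]), int(row[1]), int(row[2])
        name = str(row[3]) if len(row) > 3 and not pd.isna(row[3]) else f"peak_{i}"
        if len(row) >= 10 and int(row[9]) >= 0:
            summit = start + int(row[9])
        else:
            summit = (start + end) // 2
        peaks.append(PeakRegion(contig, start, end, summit, name))
    return peaks


def write_hits_tsv(hits: Sequence[MotifHit], path) -> None:
    df = pd.DataFrame(
        [
            {
                "seq_id": h.seq_id,
                "start": h.offset,
                "end": h.offset + h.width,
                "strand": h.strand,
                "spacer": "" if h.spacer is None else h.spacer,
                "score_bits": h.score,
                "p_value": h.p_value,
                "matched_sequence": h.matched,
            }
            for h in hits
        ],
        columns=["seq_id", "start", "end", "strand", "spacer", "score_bits",
                 "p_value", "matched_sequence"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_meme(pwms: Sequence[PWM], path, background: np.ndarray | None = None) -> None:
    """Minimal MEME motif text format."""
    bg = pwms[0].background if background is None and pwms else (
        uniform_background() if background is None else np.asarray(background, float)
    )
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{c} {f:.4f}" for c, f in zip(ALPHABET, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PWM]:
    pwms: list[PWM] = []
    bg = uniform_background()
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1] if len(line.split()) > 1 else "motif"
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            w = int(lines[i].split("w=")[1].split()[0])
            rows = []
            for k in range(w):
                rows.append([float(x) for x in lines[i + 1 + k].split()])
            mat = np.array(rows)
            mat = mat / mat.sum(axis=1, keepdims=True)
            pwms.append(PWM(mat, 0.0, bg, name=name))
            i += 1 + w
            continue
        i += 1
    return pwms
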