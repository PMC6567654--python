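"""Guide-RNA library design for Cpf1: candidate discovery, filtering,
activity ranking, off-target enumeration and library optimization.

The pipeline mirrors how a Cpf1 screen is designed against a single gene
or small locus:

1. find every TTTN-N23 targetable site on both strands;
2. drop sites with extreme protospacer GC (< 30% or > 70%) or a polyT run
   (>= 4 consecutive T in the protospacer);
3. score the survivors with the on-target activity classifier and keep the
   top fraction (default 10%);
4. enumerate genomic off-target sites with up to ``max_mismatch``
   mismatches (PAM required to match TTTN exactly), score each with the
   off-target classifier, and count predicted high-activity hits;
5. rank lexicographically by (fewest high-activity off-targets, highest
   activity, leftmost coordinate) and return the requested library size.

Coordinates are 0-based half-open on the forward strand; minus-strand site
sequences are reverse-complemented into PAM-first orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encodings import (
    SITE_LEN,
    encode_mismatch_pair,
    encode_order_k,
    reverse_complement,
)
from .nn import TrainedClassifier, predict

__all__ = [
    "CandidateSite",
    "OffTargetHit",
    "LibraryDesign",
    "find_candidate_sites",
    "apply_filters",
    "rank_and_retain",
    "enumerate_off_targets",
    "specificity_score",
    "design_library",
]

PROTOSPACER_LEN = 23
_PAM = "TTT"


@dataclass(frozen=True)
class CandidateSite:
    """A TTTN-N23 targetable site in forward-strand coordinates."""

    name: str
    start: int
    end: int
    strand: str
    sequence: str
    activity_score: float | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != SITE_LEN:
            raise ValueError("site must span exactly 27 bases")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.sequence.startswith(_PAM):
            raise ValueError(f"site sequence lacks the TTTN PAM: {self.sequence[:4]}")

    @property
    def pam(self) -> str:
        return self.sequence[:4]

    @property
    def protospacer(self) -> str:
        return self.sequence[4:]

    @property
    def gc_fraction(self) -> float:
        """GC fraction of the 23-nt protospacer (the PAM is fixed TTTN)."""
        p = self.protospacer
        return (p.count("G") + p.count("C")) / len(p)

    def has_polyt(self, run: int = 4) -> bool:
        return "T" * run in self.protospacer

    @property
    def site_id(self) -> str:
        return f"{self.name}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class OffTargetHit:
    """A genomic site similar to a guide's protospacer."""

    name: str
    start: int
    end: int
    strand: str
    sequence: str
    mismatch_count: int
    mismatch_positions: tuple[int, ...]
    predicted_score: float | None = None


@dataclass
class LibraryDesign:
    """Final ranked guide library with full provenance."""

    guides: list[CandidateSite]
    n_high_offtargets: list[int]
    specificity_scores: list[float]
    off_target_hits: dict[str, list[OffTargetHit]]
    parameters: dict
    n_candidates: int
    n_filtered: int
    n_retained: int
    warning: str | None = None

    def frame(self) -> pd.DataFrame:
        rows = []
        for g, nh, sp in zip(self.guides, self.n_high_offtargets,
                             self.specificity_scores):
            rows.append({
                "name": g.name, "start": g.start, "end": g.end,
                "strand": g.strand, "sequence": g.sequence,
                "gc_fraction": round(g.gc_fraction, 4),
                "activity_score": g.activity_score,
                "n_high_offtargets": nh, "specificity_score": sp,
            })
        return pd.DataFrame(rows)

    def to_bed(self) -> str:
        """BED6 rendering; score column = 1000 x activity, rounded."""
        lines = []
        for i, g in enumerate(self.guides, 1):
            score = int(round(1000 * (g.activity_score or 0.0)))
            lines.append(
                f"{g.name}\t{g.start}\t{g.end}\tguide_{i}\t{score}\t{g.strand}"
            )
        return "\n".join(lines) + ("\n" if lines else "")


def _scan_strand(sequence: str, name: str, strand: str):
    """Yield candidate sites reading PAM-first along one strand.

    For the minus strand the scan runs over the reverse complement and
    coordinates are mapped back to the forward strand.
    """
    seq = sequence if strand == "+" else reverse_complement(sequence)
    L = len(seq)
    for i in range(L - SITE_LEN + 1):
        window = seq[i : i + SITE_LEN]
        if not window.startswith(_PAM):
            continue
        if "N" in window:
            continue
        if strand == "+":
            start = i
        else:
            start = L - SITE_LEN - i
        yield CandidateSite(
            name=name, start=start, end=start + SITE_LEN, strand=strand,
            sequence=window,
        )


def find_candidate_sites(sequence: str, name: str = "seq") -> list[CandidateSite]:
    """All TTTN-N23 targetable sites on both strands.

    Overlapping sites are all reported; windows containing N are skipped.
    Results are sorted by (start, strand) for determinism.
    """
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains illegal characters: {sorted(bad)}")
    sites = list(_scan_strand(sequence, name, "+"))
    sites += list(_scan_strand(sequence, name, "-"))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def apply_filters(
    sites: list[CandidateSite],
    gc_min: float = 0.30,
    gc_max: float = 0.70,
    polyt_run: int = 4,
    removal_log: list | None = None,
) -> list[CandidateSite]:
    """Drop sites with extreme protospacer GC or a polyT run.

    Removal uses strict inequalities (GC < gc_min or GC > gc_max); a
    protospacer GC of exactly 30% or 70% is retained.  Each removal reason
    is appended to ``removal_log`` (site_id, reason) when given.
    Idempotent: filtering a filtered list is a no-op.
    """
    kept = []
    for site in sites:
        gc = site.gc_fraction
        if gc < gc_min or gc > gc_max:
            if removal_log is not None:
                removal_log.append((site.site_id, f"gc={gc:.3f}"))
            continue
        if site.has_polyt(polyt_run):
            if removal_log is not None:
                removal_log.append((site.site_id, "polyT"))
            continue
        kept.append(site)
    return kept


def rank_and_retain(
    sites: list[CandidateSite],
    clf_on: TrainedClassifier,
    retain_frac: float = 0.10,
) -> list[CandidateSite]:
    """Score sites with the on-target classifier and keep the top fraction.

    Retention count is ``ceil(retain_frac * n)`` with a floor of 1, so a
    tiny input still yields a candidate.  Ties are broken by coordinate so
    the ranking is invariant to input order.
    """
    if not sites:
        raise ValueError("no candidate sites to rank")
    X = np.stack([encode_order_k(s.sequence, 2).entries for s in sites])
    scores = predict(clf_on, X)
    scored = [replace(s, activity_score=float(sc)) for s, sc in zip(sites, scores)]
    scored.sort(key=lambda s: (-s.activity_score, s.start, s.strand))
    n_keep = max(1, int(np.ceil(retain_frac * len(scored))))
    return scored[:n_keep]


def _protospacer_codes(sites: list[CandidateSite]) -> np.ndarray:
    """(n_sites, 23) uint8 matrix of protospacer bytes for vectorized
    mismatch counting."""
    joined = "".join(s.protospacer for s in sites)
    return np.frombuffer(joined.encode("ascii"), dtype=np.uint8).reshape(
        len(sites), PROTOSPACER_LEN
    )


def enumerate_off_targets(
    guide: CandidateSite,
    sequences: dict[str, str] | str,
    max_mismatch: int = 4,
    sites: list[CandidateSite] | None = None,
    site_codes: np.ndarray | None = None,
) -> list[OffTargetHit]:
    """Exhaustively scan sequences for off-target sites of one guide.

    Both strands are searched for TTTN-PAM sites whose 23-nt protospacer
    differs from the guide's by at most ``max_mismatch`` substitutions
    (PAM must match TTTN exactly; mismatches are counted over the
    protospacer only).  The guide's own locus is excluded.  Each hit
    carries its 1-based mismatch positions in site coordinates, ready for
    the 12 x 27 mismatch encoding.
    """
    if not 0 <= max_mismatch <= 7:
        raise ValueError("max_mismatch must be within 0..7")
    if isinstance(sequences, str):
        sequences = {guide.name: sequences}
    if sites is None:
        sites = []
        for seq_name, seq in sequences.items():
            sites.extend(find_candidate_sites(seq.upper(), seq_name))
    if site_codes is None:
        site_codes = _protospacer_codes(sites)
    guide_codes = np.frombuffer(guide.protospacer.encode("ascii"),
                                dtype=np.uint8)
    mismatch_matrix = site_codes != guide_codes
    counts = mismatch_matrix.sum(axis=1)
    hits = []
    for i in np.flatnonzero(counts <= max_mismatch):
        site = sites[i]
        if (site.name == guide.name and site.start == guide.start
                and site.strand == guide.strand):
            continue
        mm = np.flatnonzero(mismatch_matrix[i])
        hits.append(OffTargetHit(
            name=site.name, start=site.start, end=site.end,
            strand=site.strand, sequence=site.sequence,
            mismatch_count=int(len(mm)),
            # positions are 1-based over the full 27-nt site (PAM = 1-4)
            mismatch_positions=tuple(int(p) + 5 for p in mm),
        ))
    hits.sort(key=lambda h: (h.name, h.start, h.strand))
    return hits


def specificity_score(
    guide: CandidateSite,
    hits: list[OffTargetHit],
    clf_off: TrainedClassifier,
    threshold: float | None = None,
) -> tuple[int, float, list[OffTargetHit]]:
    """Count predicted high-activity off-target sites and normalize.

    Every hit is encoded as a guide/target mismatch matrix and scored by
    the off-target classifier; hits scoring at or above the threshold are
    "high activity".  A zero-mismatch hit (an exact protospacer duplicate)
    is counted as high activity by definition: its mismatch encoding is the
    all-zero matrix, which carries no signal, while an exact match is
    maximally cleavable.  The normalized score 1 / (1 + n_high) lies in
    (0, 1] and decreases monotonically with the number of high-activity
    sites.

    Returns (n_high, normalized_score, hits with predicted scores filled).
    """
    thr = clf_off.threshold if threshold is None else threshold
    if not hits:
        return 0, 1.0, []
    X = np.stack([
        encode_mismatch_pair(guide.sequence, h.sequence).entries for h in hits
    ])
    scores = predict(clf_off, X)
    scored = [replace(h, predicted_score=float(s)) for h, s in zip(hits, scores)]
    n_high = sum(
        1 for h in scored
        if h.mismatch_count == 0 or h.predicted_score >= thr
    )
    return n_high, 1.0 / (1.0 + n_high), scored


def design_library(
    sequences: dict[str, str] | str,
    clf_on: TrainedClassifier,
    clf_off: TrainedClassifier,
    n_guides: int = 10,
    retain_frac: float = 0.10,
    max_mismatch: int = 4,
    gc_min: float = 0.30,
    gc_max: float = 0.70,
    polyt_run: int = 4,
    threshold: float | None = None,
    name: str = "seq",
) -> LibraryDesign:
    """Run the full design pipeline and return the optimized library.

    Guides are ranked lexicographically by (fewest predicted high-activity
    off-target sites, highest on-target activity, leftmost coordinate).
    If fewer than ``n_guides`` candidates survive, all survivors are
    returned with a warning flag.
    """
    if n_guides < 1:
        raise ValueError("n_guides must be >= 1")
    if isinstance(sequences, str):
        sequences = {name: sequences}
    candidates: list[CandidateSite] = []
    for seq_name, seq in sequences.items():
        candidates.extend(find_candidate_sites(seq, seq_name))
    removal_log: list = []
    filtered = apply_filters(candidates, gc_min, gc_max, polyt_run, removal_log)
    if not filtered:
        raise ValueError("no candidate sites survive the filters")
    retained = rank_and_retain(filtered, clf_on, retain_frac)

    records = []
    all_hits: dict[str, list[OffTargetHit]] = {}
    codes = _protospacer_codes(candidates)
    for site in retained:
        hits = enumerate_off_targets(site, sequences, max_mismatch,
                                     sites=candidates, site_codes=codes)
        n_high, spec_score, scored_hits = specificity_score(
            site, hits, clf_off, threshold
        )
        all_hits[site.site_id] = scored_hits
        records.append((site, n_high, spec_score))

    records.sort(key=lambda r: (r[1], -r[0].activity_score, r[0].start, r[0].strand))
    warning = None
    if len(records) < n_guides:
        warning = (
            f"only {len(records)} candidates survive; requested {n_guides}"
        )
    chosen = records[:n_guides]
    return LibraryDesign(
        guides=[r[0] for r in chosen],
        n_high_offtargets=[r[1] for r in chosen],
        specificity_scores=[r[2] for r in chosen],
        off_target_hits={r[0].site_id: all_hits[r[0].site_id] for r in chosen},
        parameters={
            "n_guides": n_guides, "retain_frac": retain_frac,
            "max_mismatch": max_mismatch, "gc_min": gc_min, "gc_max": gc_max,
            "polyt_run": polyt_run,
            "threshold": clf_off.threshold if threshold is None else threshold,
        },
        n_candidates=len(candidates),
        n_filtered=len(filtered),
        n_retained=len(retained),
        warning=warning,
    )
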