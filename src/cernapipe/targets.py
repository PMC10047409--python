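"""miRNA binding-site prediction on transcripts by seed matching.

Canonical site classes follow the standard seed-match taxonomy, defined on
miRNA positions numbered 1-based from the 5' end:

* 6mer      — Watson-Crick match of the transcript to positions 2-7;
* 7mer-m8   — WC match to positions 2-8;
* 7mer-A1   — WC match to positions 2-7 plus an 'A' opposite position 1;
* 8mer      — WC match to positions 2-8 plus an 'A' opposite position 1.

A noncanonical mode reports any transcript window whose duplex with miRNA
positions 1-10 contains a run of consecutively paired positions (WC, plus
G:U wobble outside the seed core 2-7 when enabled) of at least
``noncanonical_min_run``; this covers atypical sites lacking perfect seed
geometry. Intervals are 0-based half-open on the transcript sense strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seq import (
    DNA_ALPHABET,
    RNA_ALPHABET,
    WC_PAIRS,
    WOBBLE_PAIRS,
    as_dna,
    as_rna,
    check_alphabet,
    wc_site,
)

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer", "noncanonical")
CLASS_RANK = {cls: i for i, cls in enumerate(SITE_CLASSES)}  # lower = stronger

DEFAULT_CLASS_BONUS = {
    "8mer": 3.0,
    "7mer-m8": 2.0,
    "7mer-A1": 1.5,
    "6mer": 1.0,
    "noncanonical": 0.0,
}

_SEED_CORE = range(1, 7)  # 0-based miRNA indices of positions 2-7


@dataclass(frozen=True)
class MatcherConfig:
    classes: tuple = ("8mer", "7mer-m8", "7mer-A1", "6mer")
    allow_wobble: bool = False
    noncanonical_min_run: int = 7
    wc_weight: float = 1.0
    wobble_weight: float = 0.5
    class_bonus: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_BONUS))

    def __post_init__(self) -> None:
        unknown = set(self.classes) - set(SITE_CLASSES)
        if unknown:
            raise ValueError(f"unknown site classes: {sorted(unknown)}")
        if self.noncanonical_min_run < 6:
            raise ValueError("noncanonical_min_run must be >= 6")


@dataclass(frozen=True)
class SeedSite:
    mirna: str
    transcript: str
    start: int
    end: int
    site_class: str
    pairing: str  # site 5'->3' vs miRNA 3'->5': '|' WC, 'o' wobble, 'A' anchor
    score: float

    def interval_one_based(self) -> tuple:
        """1-based closed coordinates, the convention of genome browsers."""
        return (self.start + 1, self.end)


def score_site(site_class: str, pairing: str, cfg: MatcherConfig) -> float:
    """Additive pairing score: WC and wobble pair weights plus a class bonus.

    A transparent proxy for duplex stability; monotone over canonical
    classes (8mer >= 7mer-m8 >= 7mer-A1 >= 6mer in the same context).
    """
    return (
        cfg.wc_weight * pairing.count("|")
        + cfg.wobble_weight * pairing.count("o")
        + cfg.class_bonus.get(site_class, 0.0)
    )


def _canonical_patterns(m: str) -> dict:
    return {
        "8mer": wc_site(m[1:8]) + "A",
        "7mer-m8": wc_site(m[1:8]),
        "7mer-A1": wc_site(m[1:7]) + "A",
        "6mer": wc_site(m[1:7]),
    }


def _canonical_pairing(site_class: str) -> str:
    return {
        "8mer": "|" * 7 + "A",
        "7mer-m8": "|" * 7,
        "7mer-A1": "|" * 6 + "A",
        "6mer": "|" * 6,
    }[site_class]


def _paired(mb: str, tb: str, mirna_pos: int, allow_wobble: bool) -> str | None:
    """Pairing symbol for (miRNA base, transcript base) or None.

    Wobble pairs are honoured only outside the seed core (positions 2-7).
    """
    if (mb, tb) in WC_PAIRS:
        return "|"
    if allow_wobble and mirna_pos not in range(2, 8) and (mb, tb) in WOBBLE_PAIRS:
        return "o"
    return None


def _noncanonical_candidates(m: str, t: str, cfg: MatcherConfig) -> list:
    """Maximal paired runs of miRNA positions 1-10 against the transcript.

    For each anchor (transcript index opposite miRNA position 1) the duplex
    is read antiparallel; the longest run of consecutively paired positions
    of length >= noncanonical_min_run yields one candidate, reported on the
    transcript span of the run.
    """
    out = []
    span = min(10, len(m))
    for anchor in range(len(t)):
        symbols = []
        for j in range(span):
            ti = anchor - j
            if ti < 0:
                break
            symbols.append(_paired(m[j], t[ti], j + 1, cfg.allow_wobble))
        # longest run of paired positions
        best = None
        run_start = None
        for j, sym in enumerate(symbols + [None]):
            if sym is not None and run_start is None:
                run_start = j
            elif sym is None and run_start is not None:
                length = j - run_start
                if best is None or length > best[1] - best[0]:
                    best = (run_start, j)
                run_start = None
        if best is None:
            continue
        j1, j2 = best
        if j2 - j1 < cfg.noncanonical_min_run:
            continue
        start, end = anchor - (j2 - 1), anchor - j1 + 1
        pairing = "".join(reversed(symbols[j1:j2]))
        out.append((start, end, pairing))
    return out


def scan_sites(
    mirna_seq: str,
    transcript_seq: str,
    cfg: MatcherConfig | None = None,
    mirna_id: str = "miRNA",
    transcript_id: str = "transcript",
) -> list:
    """All binding sites of one miRNA on one transcript.

    Sites are reported left to right; a window nested inside a
    stronger-class window is not reported again (each window appears once
    under its highest class), and noncanonical runs overlapping a canonical
    site are suppressed.
    """
    cfg = cfg or MatcherConfig()
    m = as_rna(mirna_seq)
    t = as_dna(transcript_seq)
    check_alphabet(m, RNA_ALPHABET, f"miRNA {mirna_id}")
    check_alphabet(t, DNA_ALPHABET, f"transcript {transcript_id}")
    if len(m) < 18:
        raise ValueError(f"mature miRNA {mirna_id} shorter than 18 nt")
    if len(t) < 8:
        raise ValueError(f"transcript {transcript_id} shorter than 8 nt")

    patterns = _canonical_patterns(m)
    candidates = []
    for cls in SITE_CLASSES[:4]:
        if cls not in cfg.classes:
            continue
        pat = patterns[cls]
        pos = t.find(pat)
        while pos != -1:
            candidates.append((cls, pos, pos + len(pat)))
            pos = t.find(pat, pos + 1)

    kept: list = []
    for cls, start, end in sorted(candidates, key=lambda c: (CLASS_RANK[c[0]], c[1])):
        nested = any(
            ks <= start and end <= ke and CLASS_RANK[kc] < CLASS_RANK[cls]
            for kc, ks, ke in kept
        )
        if not nested:
            kept.append((cls, start, end))

    sites = [
        SeedSite(
            mirna=mirna_id,
            transcript=transcript_id,
            start=start,
            end=end,
            site_class=cls,
            pairing=_canonical_pairing(cls),
            score=score_site(cls, _canonical_pairing(cls), cfg),
        )
        for cls, start, end in kept
    ]

    if "noncanonical" in cfg.classes:
        seen = {(s.start, s.end) for s in sites}
        for start, end, pairing in _noncanonical_candidates(m, t, cfg):
            if (start, end) in seen:
                continue
            if any(start < s.end and s.start < end for s in sites):
                continue
            seen.add((start, end))
            sites.append(
                SeedSite(
                    mirna=mirna_id,
                    transcript=transcript_id,
                    start=start,
                    end=end,
                    site_class="noncanonical",
                    pairing=pairing,
                    score=score_site("noncanonical", pairing, cfg),
                )
            )

    return sorted(sites, key=lambda s: (s.start, s.end, CLASS_RANK[s.site_class]))


def site_table(mirnas: dict, transcripts: dict, cfg: MatcherConfig | None = None) -> pd.DataFrame:
    """All sites for every (miRNA, transcript) pair, deterministically ordered."""
    cfg = cfg or MatcherConfig()
    rows = []
    for mir in sorted(mirnas):
        for tx in sorted(transcripts):
            for s in scan_sites(mirnas[mir], transcripts[tx], cfg, mir, tx):
                rows.append(
                    {
                        "transcript": s.transcript,
                        "start": s.start,
                        "end": s.end,
                        "mirna": s.mirna,
                        "site_class": s.site_class,
                        "score": s.score,
                        "pairing": s.pairing,
                    }
                )
    cols = ["transcript", "start", "end", "mirna", "site_class", "score", "pairing"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["mirna", "transcript", "start"]).reset_index(drop=True)


def predict_targets(
    mirnas: dict,
    transcripts: dict,
    cfg: MatcherConfig | None = None,
    mirna_ids=None,
) -> pd.DataFrame:
    """Aggregate site predictions per (miRNA, transcript) pair.

    One row per pair with at least one site: site count, best (strongest)
    class and best score. ``mirna_ids`` restricts and validates the miRNAs
    scanned.
    """
    if mirna_ids is not None:
        missing = sorted(set(mirna_ids) - set(mirnas))
        if missing:
            raise ValueError(f"no sequence for requested miRNA(s): {missing[:5]}")
        mirnas = {m: mirnas[m] for m in mirna_ids}
    if not mirnas or not transcripts:
        return pd.DataFrame(
            columns=["mirna", "transcript", "n_sites", "best_class", "best_score"]
        )
    sites = site_table(mirnas, transcripts, cfg)
    if sites.empty:
        return pd.DataFrame(
            columns=["mirna", "transcript", "n_sites", "best_class", "best_score"]
        )
    sites["rank"] = sites["site_class"].map(CLASS_RANK)
    grouped = sites.groupby(["mirna", "transcript"], sort=True)
    out = grouped.agg(
        n_sites=("site_class", "size"),
        best_rank=("rank", "min"),
        best_score=("score", "max"),
    ).reset_index()
    out["best_class"] = [SITE_CLASSES[r] for r in out["best_rank"]]
    return out[["mirna", "transcript", "n_sites", "best_class", "best_score"]]
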