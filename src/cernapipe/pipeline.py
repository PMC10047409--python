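"""End-to-end orchestration: counts -> DE calls -> directional pairs ->
ceRNA triplets and network, plus scoring against planted truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cerna, diffexp, targets
from .containers import CountMatrix

#: canonical classes used for pair evidence in the pipeline
PAIR_CLASSES = ("8mer", "7mer-m8", "7mer-A1")
#: sponge evidence: at least this many seed sites, at least one of them 8mer
MIN_PAIR_SITES = 2


def differential_expression(
    cm: CountMatrix,
    factors: diffexp.NormalizationFactors | None = None,
    comparisons=None,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    dispersion: float | None = None,
) -> dict:
    """Annotated exact-test tables for every pairwise stage comparison."""
    factors = factors or diffexp.normalize(cm)
    comparisons = comparisons or diffexp.default_comparisons(cm)
    out = {}
    for a, b in comparisons:
        res = diffexp.exact_nb_test(cm, a, b, factors, dispersion=dispersion)
        out[f"{a}_vs_{b}"] = diffexp.call_de(
            res, p_thresh=p_thresh, lfc_thresh=lfc_thresh, keep_all=True
        )
    return out


def de_directions(annotated: pd.DataFrame) -> dict:
    """feature -> up/down for the significant features of one comparison."""
    sig = annotated[annotated["significant"]]
    return dict(zip(sig["feature"], sig["direction"]))


def strong_pairs(pair_table: pd.DataFrame) -> pd.DataFrame:
    """Sponge-evidence filter standing in for multi-predictor intersection.

    A competing transcript must carry multiple response elements for the
    shared miRNA; a lone (or weak-class) seed match is indistinguishable from
    a chance hit and is dropped.
    """
    if pair_table.empty:
        return pair_table
    keep = (pair_table["best_class"] == "8mer") & (
        pair_table["n_sites"] >= MIN_PAIR_SITES
    )
    return pair_table[keep].reset_index(drop=True)


@dataclass
class CernaResult:
    triplets: set = field(default_factory=set)
    triplets_by_comparison: dict = field(default_factory=dict)
    pairs_by_comparison: dict = field(default_factory=dict)
    network: cerna.CernaNetwork | None = None
    mirna_de: dict = field(default_factory=dict)
    transcript_de: dict = field(default_factory=dict)


def recover_cerna_network(
    mirna_cm: CountMatrix,
    transcript_cm: CountMatrix,
    mirna_seqs: dict,
    transcript_seqs: dict,
    transcript_kinds: dict,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    matcher_cfg: targets.MatcherConfig | None = None,
) -> CernaResult:
    """Run the full inference: DE screens on both matrices, seed-site
    prediction restricted to DE features, directional pairing, triplet
    assembly per comparison, and the union network."""
    cfg = matcher_cfg or targets.MatcherConfig(classes=PAIR_CLASSES)
    result = CernaResult()
    result.mirna_de = differential_expression(
        mirna_cm, p_thresh=p_thresh, lfc_thresh=lfc_thresh
    )
    result.transcript_de = differential_expression(
        transcript_cm, p_thresh=p_thresh, lfc_thresh=lfc_thresh
    )

    networks = []
    for comp in result.mirna_de:
        mirna_dirs = de_directions(result.mirna_de[comp])
        tx_dirs = {
            f: (transcript_kinds[f], d)
            for f, d in de_directions(result.transcript_de[comp]).items()
        }
        if not mirna_dirs or not tx_dirs:
            result.triplets_by_comparison[comp] = []
            continue
        pair_table = strong_pairs(
            targets.predict_targets(
                {m: mirna_seqs[m] for m in sorted(mirna_dirs)},
                {t: transcript_seqs[t] for t in sorted(tx_dirs)},
                cfg,
            )
        )
        pairs = cerna.filter_directional_pairs(mirna_dirs, tx_dirs, pair_table, comp)
        lnc_pairs = [p for p in pairs if p.kind == "lncRNA"]
        mrna_pairs = [p for p in pairs if p.kind == "mRNA"]
        triplets = cerna.assemble_triplets(lnc_pairs, mrna_pairs)
        result.pairs_by_comparison[comp] = pairs
        result.triplets_by_comparison[comp] = triplets
        result.triplets |= {t.key() for t in triplets}
        if triplets:
            networks.append(cerna.build_network(triplets))
    if networks:
        result.network = cerna.union_networks(networks)
    return result


def triplet_scores(found: set, planted) -> dict:
    """Precision/recall of recovered triplets against the planted truth."""
    planted = {tuple(t) for t in planted}
    found = set(found)
    tp = len(found & planted)
    return {
        "n_found": len(found),
        "n_planted": len(planted),
        "true_positives": tp,
        "precision": tp / len(found) if found else 0.0,
        "recall": tp / len(planted) if planted else 0.0,
    }
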