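"""Synthetic small-RNA study generator with machine-readable planted truth.

Emulates the data structure of a three-stage embryonic muscle small-RNA
experiment (three biological replicates per stage, e.g. D85/D105/D135):

* references — mature miRNAs (RNA alphabet), lncRNAs and mRNA 3'UTRs (DNA),
  plus contaminant decoys standing in for rRNA/tRNA/snoRNA filter databases;
* counts — negative-binomial feature x sample matrices whose stage means
  follow planted temporal profile shapes, with miRNA->target repression
  coupling sponge lncRNAs and mRNAs to their regulator;
* raw reads — single-end FASTQ per sample (mature sequence + 3' adapter,
  truncated to the read length) with adapter dimers, low-quality reads,
  N-containing reads, short fragments and contaminants injected at
  configured rates;
* ground truth — planted DE labels, binding-site intervals, sponge triplets
  and true library sizes, against which the pipeline is scored.

Everything is a pure function of (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import as_dna, random_seqs, wc_site
from .containers import CountMatrix

#: Temporal profile categories. "irregular" features are simulated flat
#: (not differentially expressed); the other four are planted on stage means
#: as sign patterns of consecutive log-ratios (see :func:`profile_offsets`).
PROFILE_SHAPES = ("incremental", "decreasing", "high_low_high", "low_high_low", "irregular")

# Independent deterministic RNG streams derived from the user seed.
_STREAM_REFERENCE = 1
_STREAM_COUNTS = 2
_STREAM_READS = 3

#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: Mature-length distribution peaked at 22 nt, the canonical miRNA length.
MIRNA_LENGTHS = (20, 21, 22, 23, 24)
MIRNA_LENGTH_WEIGHTS = (0.10, 0.15, 0.50, 0.15, 0.10)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_stages: int = 3
    n_replicates: int = 3
    n_mirna: int = 200
    n_lncrna: int = 300
    n_mrna: int = 2000
    frac_de: float = 0.3
    #: weights over PROFILE_SHAPES; the "irregular" weight is ignored when
    #: planting DE features (irregular == flat == not DE).
    profile_mix: tuple = (0.3, 0.3, 0.2, 0.2, 0.0)
    n_triplets: int = 50
    effect_size: float = 2.0
    nb_dispersion: float = 0.1
    repression_strength: float = 0.5
    sites_per_target: tuple = (2, 3)
    lib_size_range: tuple = (300_000, 600_000)
    lncrna_length: int = 500
    utr_length: int = 500
    n_contaminants: int = 20
    contaminant_length: int = 30
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    contaminant_frac: float = 0.05
    lowqual_frac: float = 0.02
    n_base_frac: float = 0.01
    short_frac: float = 0.02
    dimer_frac: float = 0.01
    three_prime_variant_frac: float = 0.0

    def __post_init__(self) -> None:
        fracs = {
            "frac_de": self.frac_de,
            "contaminant_frac": self.contaminant_frac,
            "lowqual_frac": self.lowqual_frac,
            "n_base_frac": self.n_base_frac,
            "short_frac": self.short_frac,
            "dimer_frac": self.dimer_frac,
            "three_prime_variant_frac": self.three_prime_variant_frac,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.noise_frac >= 1.0:
            raise ValueError("noise fractions must sum to < 1")
        if self.n_stages < 2:
            raise ValueError("need at least two stages")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0.0 <= self.repression_strength < 1.0:
            raise ValueError("repression_strength must be in [0, 1)")
        if min(self.n_mirna, self.n_lncrna, self.n_mrna) < 1:
            raise ValueError("feature counts must be >= 1")
        lo, hi = self.sites_per_target
        if not (1 <= lo <= hi):
            raise ValueError("sites_per_target must satisfy 1 <= lo <= hi")

    @property
    def noise_frac(self) -> float:
        return (
            self.contaminant_frac
            + self.lowqual_frac
            + self.n_base_frac
            + self.short_frac
            + self.dimer_frac
        )

    @property
    def stage_labels(self) -> tuple:
        if self.n_stages == 3:
            return ("D85", "D105", "D135")
        return tuple(f"S{i + 1}" for i in range(self.n_stages))

    @property
    def sample_ids(self) -> tuple:
        return tuple(
            f"{stage}-{rep + 1}"
            for stage in self.stage_labels
            for rep in range(self.n_replicates)
        )

    def comparisons(self) -> list:
        """All ordered pairwise stage comparisons (earlier vs later)."""
        stages = self.stage_labels
        return [
            (stages[i], stages[j])
            for i in range(len(stages))
            for j in range(i + 1, len(stages))
        ]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("profile_mix", "sites_per_target", "lib_size_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ReferenceSet:
    """Named sequences per RNA class; names unique within and across classes."""

    mirnas: list
    lncrnas: list
    mrna_utrs: list
    contaminants: list

    def __post_init__(self) -> None:
        names = [n for group in self.all_groups().values() for n, _ in group]
        if len(names) != len(set(names)):
            raise ValueError("reference names must be unique across classes")

    def all_groups(self) -> dict:
        return {
            "mirnas": self.mirnas,
            "lncrnas": self.lncrnas,
            "mrna_utrs": self.mrna_utrs,
            "contaminants": self.contaminants,
        }

    @property
    def mirna_seqs(self) -> dict:
        return dict(self.mirnas)

    @property
    def transcript_seqs(self) -> dict:
        return dict(self.lncrnas) | dict(self.mrna_utrs)

    @property
    def transcript_kinds(self) -> dict:
        kinds = {name: "lncRNA" for name, _ in self.lncrnas}
        kinds.update({name: "mRNA" for name, _ in self.mrna_utrs})
        return kinds

    def write_fasta(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for group, entries in self.all_groups().items():
            path = outdir / f"{group}.fasta"
            records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
            SeqIO.write(records, str(path), "fasta")
            paths[group] = path
        return paths

    @classmethod
    def from_fasta(cls, mirnas, lncrnas, mrna_utrs, contaminants=None) -> "ReferenceSet":
        def load(path):
            if path is None:
                return []
            return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]

        return cls(load(mirnas), load(lncrnas), load(mrna_utrs), load(contaminants))


@dataclass
class GroundTruth:
    """Planted labels the pipeline is scored against.

    ``de_labels``: feature -> {"shape": ..., "directions": {comparison: up/down}}
    ``planted_sites``: dicts with mirna, transcript, start, end (0-based
    half-open on the transcript sense strand) and site_class.
    ``planted_triplets``: (lncRNA, miRNA, mRNA) tuples.
    ``true_lib_factors``: sample -> miRNA-library size actually simulated.
    """

    de_labels: dict
    planted_sites: list
    planted_triplets: list
    true_lib_factors: dict
    transcript_lib_sizes: dict
    mirna_names: list = field(default_factory=list)
    lncrna_names: list = field(default_factory=list)
    mrna_names: list = field(default_factory=list)

    def sites_for(self, mirna: str, transcript: str) -> list:
        return [
            s
            for s in self.planted_sites
            if s["mirna"] == mirna and s["transcript"] == transcript
        ]

    def validate(self) -> None:
        planted_pairs = {(s["mirna"], s["transcript"]) for s in self.planted_sites}
        for lnc, mir, mrna in self.planted_triplets:
            if (mir, lnc) not in planted_pairs or (mir, mrna) not in planted_pairs:
                raise ValueError(f"triplet ({lnc}, {mir}, {mrna}) lacks planted sites")
        for feature, label in self.de_labels.items():
            if label["shape"] == "irregular":
                raise ValueError(f"DE feature {feature} has a flat profile shape")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        raw["planted_triplets"] = [tuple(t) for t in raw["planted_triplets"]]
        return cls(**raw)


def profile_offsets(shape: str, effect_size: float) -> tuple:
    """Per-stage log2 offsets (relative to stage 1) for a 3-stage profile.

    The extreme-stage contrast of the monotone shapes equals ``effect_size``;
    the peak/trough shapes swing by the full ``effect_size`` and return.
    """
    e = float(effect_size)
    table = {
        "incremental": (0.0, e / 2.0, e),
        "decreasing": (0.0, -e / 2.0, -e),
        "high_low_high": (0.0, -e, 0.0),
        "low_high_low": (0.0, e, 0.0),
        "irregular": (0.0, 0.0, 0.0),
    }
    return table[shape]


def shape_from_offsets(offsets, tol: float = 1e-9) -> str:
    d1 = offsets[1] - offsets[0]
    d2 = offsets[2] - offsets[1]
    s1 = 0 if abs(d1) <= tol else (1 if d1 > 0 else -1)
    s2 = 0 if abs(d2) <= tol else (1 if d2 > 0 else -1)
    return {
        (1, 1): "incremental",
        (-1, -1): "decreasing",
        (-1, 1): "high_low_high",
        (1, -1): "low_high_low",
    }.get((s1, s2), "irregular")


def directions_from_offsets(offsets, stage_labels, tol: float = 1e-9) -> dict:
    """Per-comparison up/down/none labels implied by planted stage offsets."""
    out = {}
    for i in range(len(stage_labels)):
        for j in range(i + 1, len(stage_labels)):
            diff = offsets[j] - offsets[i]
            label = f"{stage_labels[i]}_vs_{stage_labels[j]}"
            out[label] = "none" if abs(diff) <= tol else ("up" if diff > 0 else "down")
    return out


def _plant_sites(rng, seq_list, site: str, k: int, occupied: list, transcript: str) -> list:
    """Overwrite ``k`` non-overlapping copies of ``site`` into a mutable sequence."""
    length = len(seq_list)
    w = len(site)
    intervals = []
    for _ in range(k):
        placed = False
        for _attempt in range(200):
            if length < w:
                break
            pos = int(rng.integers(0, length - w + 1))
            if all(pos + w <= s or pos >= e for s, e in occupied):
                seq_list[pos : pos + w] = list(site)
                occupied.append((pos, pos + w))
                intervals.append((pos, pos + w))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"transcript {transcript} too short to host {k} requested sites"
            )
    return intervals


def build_reference(config: SimulationConfig):
    """Generate references and the planted ground truth.

    Returns ``(ReferenceSet, GroundTruth)``. For every planted (miRNA,
    transcript) pair the transcript carries 8mer seed sites (the reverse
    complement of miRNA positions 2-8 followed by an A opposite position 1)
    at the exact recorded 0-based half-open intervals.
    """
    rng = np.random.default_rng([config.seed, _STREAM_REFERENCE])

    def mk_names(prefix, n):
        width = max(3, len(str(n)))
        return [f"{prefix}-{i + 1:0{width}d}" for i in range(n)]

    mirna_names = mk_names("sim-miR", config.n_mirna)
    lnc_names = mk_names("sim-lnc", config.n_lncrna)
    mrna_names = mk_names("sim-mrna", config.n_mrna)
    cont_names = mk_names("sim-rfam", config.n_contaminants)

    mirna_lengths = rng.choice(MIRNA_LENGTHS, size=config.n_mirna, p=MIRNA_LENGTH_WEIGHTS)
    mirna_seqs = random_seqs(rng, mirna_lengths, "ACGU")
    lnc_seqs = [list(s) for s in random_seqs(rng, [config.lncrna_length] * config.n_lncrna)]
    mrna_seqs = [list(s) for s in random_seqs(rng, [config.utr_length] * config.n_mrna)]
    cont_seqs = random_seqs(rng, [config.contaminant_length] * config.n_contaminants)

    n_de = int(round(config.frac_de * config.n_mirna))
    if config.n_triplets > n_de:
        raise ValueError(
            f"cannot plant {config.n_triplets} triplets with only {n_de} DE miRNAs"
        )
    de_idx = np.sort(rng.choice(config.n_mirna, size=n_de, replace=False))
    weights = np.asarray(config.profile_mix[:4], dtype=float)
    if n_de and weights.sum() <= 0:
        raise ValueError("profile_mix assigns no weight to any non-flat shape")
    shapes = (
        rng.choice(PROFILE_SHAPES[:4], size=n_de, p=weights / weights.sum())
        if n_de
        else np.array([], dtype=object)
    )

    stage_labels = config.stage_labels
    de_labels = {}
    for idx, shape in zip(de_idx, shapes):
        offs = profile_offsets(str(shape), config.effect_size)
        de_labels[mirna_names[idx]] = {
            "shape": str(shape),
            "directions": directions_from_offsets(offs, stage_labels),
        }

    # Sponge triplets: distinct miRNA / lncRNA / mRNA per triplet.
    triplet_mirs = rng.choice(de_idx, size=config.n_triplets, replace=False)
    triplet_lncs = rng.choice(config.n_lncrna, size=config.n_triplets, replace=False)
    triplet_mrnas = rng.choice(config.n_mrna, size=config.n_triplets, replace=False)

    lo, hi = config.sites_per_target
    planted_sites = []
    planted_triplets = []
    occupied_lnc = defaultdict(list)
    occupied_mrna = defaultdict(list)
    r = config.repression_strength
    for mi, li, gi in zip(triplet_mirs, triplet_lncs, triplet_mrnas):
        mir_name = mirna_names[mi]
        site = wc_site(mirna_seqs[mi][1:8]) + "A"  # 8mer
        for names, seqs, occ, ti in (
            (lnc_names, lnc_seqs, occupied_lnc, li),
            (mrna_names, mrna_seqs, occupied_mrna, gi),
        ):
            k = int(rng.integers(lo, hi + 1))
            intervals = _plant_sites(rng, seqs[ti], site, k, occ[ti], names[ti])
            for start, end in intervals:
                planted_sites.append(
                    {
                        "mirna": mir_name,
                        "transcript": names[ti],
                        "start": start,
                        "end": end,
                        "site_class": "8mer",
                    }
                )
            # Repression couples the target's stage profile to its regulator:
            # per regulator doubling, the target mean drops by the fraction r.
            mir_offs = np.array(profile_offsets(de_labels[mir_name]["shape"], config.effect_size))
            t_offs = mir_offs * np.log2(1.0 - r) if r > 0 else np.zeros(3)
            if np.abs(t_offs).max() > 1e-9:
                de_labels[names[ti]] = {
                    "shape": shape_from_offsets(t_offs),
                    "directions": directions_from_offsets(t_offs, stage_labels),
                }
        planted_triplets.append((lnc_names[li], mir_name, mrna_names[gi]))

    lib_lo, lib_hi = config.lib_size_range
    sample_ids = config.sample_ids
    true_lib = {s: int(rng.integers(lib_lo, lib_hi + 1)) for s in sample_ids}
    transcript_lib = {s: int(rng.integers(lib_lo, lib_hi + 1)) for s in sample_ids}

    refs = ReferenceSet(
        mirnas=list(zip(mirna_names, mirna_seqs)),
        lncrnas=[(n, "".join(s)) for n, s in zip(lnc_names, lnc_seqs)],
        mrna_utrs=[(n, "".join(s)) for n, s in zip(mrna_names, mrna_seqs)],
        contaminants=list(zip(cont_names, cont_seqs)),
    )
    truth = GroundTruth(
        de_labels=de_labels,
        planted_sites=planted_sites,
        planted_triplets=planted_triplets,
        true_lib_factors=true_lib,
        transcript_lib_sizes=transcript_lib,
        mirna_names=mirna_names,
        lncrna_names=lnc_names,
        mrna_names=mrna_names,
    )
    truth.validate()
    return refs, truth


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(config: SimulationConfig, truth: GroundTruth):
    """NB count matrices (miRNA, transcript) following the planted profiles.

    Stage means of planted-DE miRNAs follow their profile shape with the
    configured |log2FC| between designated stages; planted targets shift in
    the opposite direction with magnitude scaled by ``repression_strength``
    (see :func:`build_reference`); all other features are flat in expectation.
    """
    if config.repression_strength >= 1:
        raise ValueError("repression_strength must be < 1")
    rng = np.random.default_rng([config.seed, _STREAM_COUNTS])
    stage_labels = config.stage_labels
    sample_ids = list(config.sample_ids)
    stage_of = np.array(
        [stage_labels.index(s.rsplit("-", 1)[0]) for s in sample_ids]
    )
    r = config.repression_strength

    mir_offsets = {}
    for name in truth.mirna_names:
        label = truth.de_labels.get(name)
        shape = label["shape"] if label else "irregular"
        mir_offsets[name] = np.array(profile_offsets(shape, config.effect_size))

    transcript_names = truth.lncrna_names + truth.mrna_names
    t_offsets = {name: np.zeros(config.n_stages) for name in transcript_names}
    if r > 0:
        seen = set()
        for s in truth.planted_sites:
            key = (s["mirna"], s["transcript"])
            if key in seen:
                continue  # repression acts once per regulator, not per site
            seen.add(key)
            t_offsets[s["transcript"]] = (
                t_offsets[s["transcript"]] + mir_offsets[s["mirna"]] * np.log2(1.0 - r)
            )

    def make_matrix(names, offsets, lib_sizes):
        n = len(names)
        rel = rng.lognormal(mean=0.0, sigma=1.0, size=n)
        rel /= rel.sum()
        off = np.stack([offsets[name] for name in names])  # n x stages
        libs = np.array([lib_sizes[s] for s in sample_ids], dtype=float)
        mean = rel[:, None] * np.exp2(off[:, stage_of]) * libs[None, :]
        counts = _nb_draw(rng, mean, config.nb_dispersion)
        df = pd.DataFrame(counts, index=names, columns=sample_ids, dtype=np.int64)
        meta = pd.DataFrame(
            {
                "stage": [stage_labels[k] for k in stage_of],
                "replicate": [int(s.rsplit("-", 1)[1]) for s in sample_ids],
            },
            index=pd.Index(sample_ids, name="sample"),
        )
        return CountMatrix(df, meta)

    mirna_cm = make_matrix(truth.mirna_names, mir_offsets, truth.true_lib_factors)
    transcript_cm = make_matrix(transcript_names, t_offsets, truth.transcript_lib_sizes)
    return mirna_cm, transcript_cm


_HIGH_Q = "I"  # Phred 40
_LOW_Q = "+"  # Phred 10, mean quality below any sensible threshold


def simulate_reads(config: SimulationConfig, refs: ReferenceSet, counts: CountMatrix, outdir):
    """Write one FASTQ (Phred+33) per sample; return a per-sample manifest.

    Each miRNA contributes exactly its count of signal reads (mature DNA
    sequence + adapter, truncated to the read length); adapter dimers,
    low-quality, N-containing, short-fragment and contaminant reads are
    injected so each noise class makes up its configured fraction of the raw
    total. Raw total = column sum + noise reads, exactly.
    """
    if len(config.adapter) < 6:
        raise ValueError("adapter must be at least 6 nt to be detectable downstream")
    mirna_seqs = {name: as_dna(seq) for name, seq in refs.mirnas}
    missing = [f for f in counts.features if f not in mirna_seqs]
    if missing:
        raise ValueError(f"count matrix rows not in miRNA reference: {missing[:5]}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, _STREAM_READS])
    adapter = config.adapter
    rl = config.read_length

    def read_of(insert: str, qual_char: str = _HIGH_Q):
        seq = (insert + adapter)[:rl]
        return seq, qual_char * len(seq)

    cont_seqs = [seq for _, seq in refs.contaminants]
    manifest = {}
    for sample in counts.counts.columns:
        col = counts.counts[sample]
        reads = []
        for name, c in col.items():
            c = int(c)
            if c == 0:
                continue
            mature = mirna_seqs[name]
            n_var = int(round(config.three_prime_variant_frac * c))
            for i in range(c):
                if i < n_var:
                    if rng.random() < 0.5 and len(mature) > 19:
                        insert = mature[:-1]
                    else:
                        insert = mature + random_seqs(rng, [1])[0]
                else:
                    insert = mature
                reads.append(read_of(insert))
        n_valid = int(col.sum())
        n_raw_target = n_valid / (1.0 - config.noise_frac) if n_valid else 0.0
        noise_plan = {
            "contaminant": int(round(config.contaminant_frac * n_raw_target)),
            "lowqual": int(round(config.lowqual_frac * n_raw_target)),
            "n_base": int(round(config.n_base_frac * n_raw_target)),
            "short": int(round(config.short_frac * n_raw_target)),
            "dimer": int(round(config.dimer_frac * n_raw_target)),
        }
        matures = list(mirna_seqs.values())
        for _ in range(noise_plan["contaminant"]):
            reads.append(read_of(cont_seqs[int(rng.integers(0, len(cont_seqs)))]))
        for _ in range(noise_plan["lowqual"]):
            insert = matures[int(rng.integers(0, len(matures)))]
            seq = (insert + adapter)[:rl]
            reads.append((seq, _LOW_Q * len(seq)))
        for _ in range(noise_plan["n_base"]):
            insert = list(matures[int(rng.integers(0, len(matures)))])
            insert[int(rng.integers(0, len(insert)))] = "N"
            reads.append(read_of("".join(insert)))
        for _ in range(noise_plan["short"]):
            reads.append(read_of(random_seqs(rng, [int(rng.integers(5, 18))])[0]))
        for _ in range(noise_plan["dimer"]):
            reads.append(read_of(""))

        order = rng.permutation(len(reads))
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as fh:
            for serial, k in enumerate(order):
                seq, qual = reads[k]
                fh.write(f"@{sample}:{serial}\n{seq}\n+\n{qual}\n")
        manifest[sample] = {
            "path": str(path),
            "n_reads": len(reads),
            "n_signal": n_valid,
            **{f"n_{k}": v for k, v in noise_plan.items()},
        }
    return manifest
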