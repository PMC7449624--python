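"""Synthetic amplicon communities with known strain-level ground truth.

This module emulates the data a deep amplicon strain-typing experiment
produces: a handful of short (<500 bp) protein-coding marker genes, a few
hundred host individuals ("bees") sampled from several locations, and for
each (bee, marker) a pool of merged single-fragment reads at high coverage.
The planted structure mirrors what is observed in the honey-bee gut
microbiome: strains come in small clusters of closely related haplotypes
(typically one SNP apart) that travel together across hosts, most hosts
carry a single cluster, and the relative abundances of the strains within a
cluster are conserved across every host that carries it.

Everything is deterministic given the seeds, down to the bytes of the
emitted FASTQ, so tests can treat the generator as an oracle.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_ALPH = np.array(list(ALPHABET))

#: Bees sampled per location in the study design this generator emulates.
DEFAULT_LOCATION_SIZES: dict[str, int] = {
    "Texas": 103,
    "Tennessee": 21,
    "Utah": 9,
    "Florida": 11,
}

#: Marker gene names (two per symbiont species) and desk-realistic lengths.
DEFAULT_MARKER_LENGTHS: dict[str, int] = {
    "guaA": 450,
    "gluS": 444,
    "pflA": 456,
    "rimM": 453,
}


@dataclass(frozen=True)
class MarkerReference:
    """One amplicon reference sequence plus its reading-frame offset.

    ``frame_offset`` is the number of bases preceding the first complete
    codon (0-2); it anchors codon-position bookkeeping for every SNP called
    against this reference.
    """

    name: str
    sequence: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not 30 <= len(self.sequence) < 500:
            raise ValueError(
                f"marker {self.name!r}: length {len(self.sequence)} outside [30, 500)"
            )
        if set(self.sequence) - set(ALPHABET):
            bad = sorted(set(self.sequence) - set(ALPHABET))
            raise ValueError(f"marker {self.name!r}: ambiguity codes {bad} not allowed")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0-2, got {self.frame_offset}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSimParams:
    """Knobs for read simulation.

    coverage_mean:
        Expected reads per (bee, marker); study-scale default 46,000.
    coverage_dispersion:
        Negative-binomial size parameter; smaller = more overdispersed.
    error_rate:
        Independent per-base substitution probability.
    phred_high / phred_low:
        Quality assigned to correct / erroneous bases, so that the
        downstream mean-quality filter can be exercised deliberately.
    """

    coverage_mean: float = 46_000.0
    coverage_dispersion: float = 8.0
    error_rate: float = 0.001
    phred_high: int = 40
    phred_low: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError(f"error_rate must be in [0, 0.05], got {self.error_rate}")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be > 0")
        for q in (self.phred_high, self.phred_low):
            if not 0 <= q <= 60:
                raise ValueError(f"Phred values must be in [0, 60], got {q}")


@dataclass
class TruthSet:
    """Planted ground truth: references, clusters, assignments, profiles.

    clusters[marker][c] is the list of member haplotype sequences of cluster
    ``c``; abundance_profiles[marker][c] the shared relative frequencies of
    those members (one profile per cluster, used by every bee carrying it).
    bee_clusters[bee][marker] lists the cluster indices the bee carries
    (one by default, occasionally two).  cryptic_carriage[bee][marker] is a
    list of (sequence, frequency) pairs planted below the calling threshold.
    """

    references: dict[str, MarkerReference]
    clusters: dict[str, list[list[str]]]
    abundance_profiles: dict[str, list[np.ndarray]]
    bee_locations: dict[str, str]
    bee_clusters: dict[str, dict[str, list[int]]]
    cryptic_carriage: dict[str, dict[str, list[tuple[str, float]]]] = field(
        default_factory=dict
    )

    # -- derived views ----------------------------------------------------
    @property
    def bees(self) -> list[str]:
        return list(self.bee_locations)

    @property
    def markers(self) -> list[str]:
        return list(self.references)

    def strain_sequences(self, marker: str) -> list[str]:
        """All planted strain sequences for a marker, cluster by cluster."""
        return [s for cluster in self.clusters[marker] for s in cluster]

    def partition(self, marker: str) -> dict[str, int]:
        """Map each planted sequence to its cluster index."""
        return {
            seq: c
            for c, cluster in enumerate(self.clusters[marker])
            for seq in cluster
        }

    def composition(self, bee: str, marker: str) -> dict[str, float]:
        """Planted relative strain frequencies in one (bee, marker).

        Carried clusters are mixed with equal weight; cryptic carriage is
        layered on top, scaling the main composition down so the total
        stays 1.
        """
        carried = self.bee_clusters[bee][marker]
        w = 1.0 / len(carried)
        comp: dict[str, float] = {}
        for c in carried:
            for seq, f in zip(self.clusters[marker][c], self.abundance_profiles[marker][c]):
                comp[seq] = comp.get(seq, 0.0) + w * float(f)
        extras = self.cryptic_carriage.get(bee, {}).get(marker, [])
        if extras:
            spare = sum(f for _, f in extras)
            if spare >= 1.0:
                raise ValueError("cryptic carriage frequencies sum to >= 1")
            comp = {s: f * (1.0 - spare) for s, f in comp.items()}
            for seq, f in extras:
                comp[seq] = comp.get(seq, 0.0) + f
        return comp

    def expected_strains(self, bee: str, marker: str, threshold: float = 0.01) -> set[str]:
        """Sequences planted above the calling threshold in this bee."""
        return {s for s, f in self.composition(bee, marker).items() if f > threshold}


def make_marker_reference(
    length: int, frame_offset: int = 0, seed: int = 0, name: str = "marker"
) -> MarkerReference:
    """Uniform-random marker reference; deterministic for a fixed seed."""
    if not 30 <= length < 500:
        raise ValueError(f"length must be in [30, 500), got {length}")
    rng = np.random.default_rng(seed)
    seq = "".join(_ALPH[rng.integers(0, 4, size=length)])
    return MarkerReference(name=name, sequence=seq, frame_offset=frame_offset)


def _mutate(sequence: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    """Substitute each 1-based position with a uniform different base."""
    chars = list(sequence)
    for pos in positions:
        old = chars[pos - 1]
        alternatives = [b for b in ALPHABET if b != old]
        chars[pos - 1] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def default_references(seed: int = 0) -> dict[str, MarkerReference]:
    """The four default marker references (two per symbiont species)."""
    rng = np.random.default_rng(seed)
    refs = {}
    for name, length in DEFAULT_MARKER_LENGTHS.items():
        refs[name] = make_marker_reference(
            length, frame_offset=0, seed=int(rng.integers(0, 2**31)), name=name
        )
    return refs


def make_truth(
    n_bees: int,
    locations: Mapping[str, int],
    n_clusters: int,
    strains_per_cluster: int,
    within_cluster_snps: int = 1,
    between_cluster_snps: int = 8,
    two_cluster_fraction: float = 0.1,
    location_bias: float = 0.0,
    references: Mapping[str, MarkerReference] | None = None,
    min_member_freq: float = 0.05,
    seed: int = 0,
) -> TruthSet:
    """Plant cluster structure, bee assignments, and abundance profiles.

    Each cluster is founded by mutating the reference at
    ``between_cluster_snps`` random sites; the other members each carry
    ``within_cluster_snps`` additional private substitutions of the founder,
    so members sit 1-2 SNPs apart for the default of one.  Clusters are
    spread across locations independently of geography unless
    ``location_bias`` > 0 (at 1.0 every cluster is exclusive to one
    location).  A fraction of bees carry two clusters mixed 50/50; all other
    bees carry exactly one cluster per marker, reproducing its shared
    abundance profile.
    """
    if sum(locations.values()) != n_bees:
        raise ValueError("location sizes must sum to n_bees")
    if strains_per_cluster < 1:
        raise ValueError("strains_per_cluster must be >= 1")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if within_cluster_snps < 1:
        raise ValueError("within_cluster_snps must be >= 1")
    if not 0.0 <= two_cluster_fraction <= 1.0:
        raise ValueError("two_cluster_fraction must be in [0, 1]")
    if not 0.0 <= location_bias <= 1.0:
        raise ValueError("location_bias must be in [0, 1]")
    if strains_per_cluster * min_member_freq >= 1.0:
        raise ValueError("min_member_freq too large for strains_per_cluster")

    rng = np.random.default_rng(seed)
    if references is None:
        references = default_references(seed=int(rng.integers(0, 2**31)))
    references = dict(references)

    bees = [f"bee{i:03d}" for i in range(n_bees)]
    bee_locations: dict[str, str] = {}
    i = 0
    for loc, size in locations.items():
        for _ in range(size):
            bee_locations[bees[i]] = loc
            i += 1

    loc_names = list(locations)
    # Deal clusters round-robin to "home" locations (used only under bias).
    homes = [loc_names[c % len(loc_names)] for c in range(n_clusters)]

    clusters: dict[str, list[list[str]]] = {}
    profiles: dict[str, list[np.ndarray]] = {}
    bee_clusters: dict[str, dict[str, list[int]]] = {b: {} for b in bees}

    for marker, ref in references.items():
        L = len(ref)
        if between_cluster_snps > L or within_cluster_snps > L:
            raise ValueError("SNP counts exceed marker length")
        seen: set[str] = {ref.sequence}
        marker_clusters: list[list[str]] = []
        marker_profiles: list[np.ndarray] = []
        for _c in range(n_clusters):
            while True:
                pos = rng.choice(L, size=between_cluster_snps, replace=False) + 1
                founder = _mutate(ref.sequence, pos, rng)
                if founder not in seen:
                    break
            members = [founder]
            seen.add(founder)
            while len(members) < strains_per_cluster:
                pos = rng.choice(L, size=within_cluster_snps, replace=False) + 1
                s = _mutate(founder, pos, rng)
                if s not in seen:
                    members.append(s)
                    seen.add(s)
            raw = rng.dirichlet(np.full(strains_per_cluster, 3.0))
            prof = min_member_freq + (1.0 - strains_per_cluster * min_member_freq) * raw
            marker_clusters.append(members)
            marker_profiles.append(prof)
        clusters[marker] = marker_clusters
        profiles[marker] = marker_profiles

        two = rng.random(n_bees) < two_cluster_fraction
        for b_i, bee in enumerate(bees):
            pool = list(range(n_clusters))
            if location_bias > 0 and rng.random() < location_bias:
                local = [c for c in pool if homes[c] == bee_locations[bee]]
                if local:
                    pool = local
            c1 = int(pool[rng.integers(0, len(pool))])
            carried = [c1]
            if two[b_i] and len(pool) > 1:
                others = [c for c in pool if c != c1]
                carried.append(int(others[rng.integers(0, len(others))]))
            bee_clusters[bee][marker] = carried

    return TruthSet(
        references=references,
        clusters=clusters,
        abundance_profiles=profiles,
        bee_locations=bee_locations,
        bee_clusters=bee_clusters,
    )


def add_cryptic_carriage(
    truth: TruthSet,
    fold: int = 5,
    freq: float = 0.005,
    seed: int = 0,
) -> TruthSet:
    """Plant sub-threshold carriage so relaxed prevalence is ``fold``x strict.

    For every cluster, (fold - 1) times as many non-carrier bees as there
    are carriers receive each member strain at frequency ``freq`` (kept well
    below the 1% calling threshold).  Mutates and returns ``truth``.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    if not 0 < freq < 0.01:
        raise ValueError("cryptic freq must sit below the 1% calling threshold")
    rng = np.random.default_rng(seed)
    for marker in truth.markers:
        n_clusters = len(truth.clusters[marker])
        for c in range(n_clusters):
            carriers = [b for b in truth.bees if c in truth.bee_clusters[b][marker]]
            others = [b for b in truth.bees if c not in truth.bee_clusters[b][marker]]
            need = (fold - 1) * len(carriers)
            if need > len(others):
                raise ValueError(
                    f"not enough non-carriers for cluster {c} of {marker}: "
                    f"need {need}, have {len(others)}"
                )
            chosen = rng.choice(len(others), size=need, replace=False)
            for j in chosen:
                bee = others[int(j)]
                entries = truth.cryptic_carriage.setdefault(bee, {}).setdefault(marker, [])
                for seq in truth.clusters[marker][c]:
                    entries.append((seq, freq))
    return truth


@dataclass
class ReadSimResult:
    """Simulated reads plus the metadata needed to analyse them."""

    truth: TruthSet
    params: ReadSimParams
    #: (bee, marker) -> list of (read_id, bases, quality string, Phred+33)
    reads: dict[tuple[str, str], list[tuple[str, str, str]]]
    metadata: pd.DataFrame  # columns: sample_id, location

    def pools(self) -> dict[tuple[str, str], list[str]]:
        """Raw base strings per (bee, marker) — the full unfiltered pool."""
        return {key: [bases for _, bases, _ in recs] for key, recs in self.reads.items()}

    def quality_reads(self):
        """Reads as :class:`mastkit.strain_caller.QualityRead` objects."""
        from .strain_caller import QualityRead

        out = {}
        for key, recs in self.reads.items():
            out[key] = [
                QualityRead(rid, bases, np.frombuffer(qual.encode(), np.uint8) - 33)
                for rid, bases, qual in recs
            ]
        return out

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write FASTQ per (bee, marker), references, metadata and truth tables."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        reads_dir = out / "reads"
        reads_dir.mkdir(exist_ok=True)
        for (bee, marker), recs in self.reads.items():
            records = []
            for rid, bases, qual in recs:
                rec = SeqRecord(Seq(bases), id=rid, description="")
                rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
                records.append(rec)
            SeqIO.write(records, reads_dir / f"{bee}_{marker}.fastq", "fastq")
        write_references(self.truth.references, out / "references.fasta",
                         out / "frame_offsets.tsv")
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        rows = []
        for marker in self.truth.markers:
            for c, members in enumerate(self.truth.clusters[marker]):
                for seq, f in zip(members, self.truth.abundance_profiles[marker][c]):
                    rows.append((marker, c, seq, f))
        pd.DataFrame(rows, columns=["marker", "cluster", "sequence", "profile_freq"]).to_csv(
            out / "truth_strains.tsv", sep="\t", index=False
        )
        return {
            "reads": reads_dir,
            "references": out / "references.fasta",
            "frame_offsets": out / "frame_offsets.tsv",
            "metadata": out / "metadata.tsv",
            "truth": out / "truth_strains.tsv",
        }


def write_references(
    references: Mapping[str, MarkerReference],
    fasta_path: str | Path,
    offsets_path: str | Path | None = None,
) -> None:
    records = [
        SeqRecord(Seq(ref.sequence), id=name, description=f"frame_offset={ref.frame_offset}")
        for name, ref in references.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if offsets_path is not None:
        pd.DataFrame(
            [(name, ref.frame_offset) for name, ref in references.items()],
            columns=["marker", "frame_offset"],
        ).to_csv(offsets_path, sep="\t", index=False)


def read_references(
    fasta_path: str | Path, offsets_path: str | Path | None = None
) -> dict[str, MarkerReference]:
    offsets: dict[str, int] = {}
    if offsets_path is not None and Path(offsets_path).exists():
        df = pd.read_csv(offsets_path, sep="\t")
        offsets = dict(zip(df["marker"], df["frame_offset"].astype(int)))
    refs = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        off = offsets.get(rec.id)
        if off is None:
            off = 0
            for tok in rec.description.split():
                if tok.startswith("frame_offset="):
                    off = int(tok.split("=", 1)[1])
        refs[rec.id] = MarkerReference(rec.id, str(rec.seq).upper(), off)
    return refs


def simulate_reads(
    truth: TruthSet,
    params: ReadSimParams | None = None,
    out_dir: str | Path | None = None,
) -> ReadSimResult:
    """Draw error-bearing reads for every (bee, marker).

    Per (bee, marker): coverage ~ negative binomial (mean, dispersion);
    reads are allocated to the bee's planted strains multinomially by its
    abundance profile; each base then flips to a uniform alternative with
    probability ``error_rate``.  Erroneous bases carry ``phred_low``,
    correct bases ``phred_high``.  Fully deterministic given the seed.
    """
    params = params or ReadSimParams()
    rng = np.random.default_rng(params.seed)
    mu, r = params.coverage_mean, params.coverage_dispersion
    p_nb = r / (r + mu)
    qhigh = chr(params.phred_high + 33)
    qlow = chr(params.phred_low + 33)

    reads: dict[tuple[str, str], list[tuple[str, str, str]]] = {}
    for bee in truth.bees:
        for marker in truth.markers:
            cov = int(rng.negative_binomial(r, p_nb))
            comp = truth.composition(bee, marker)
            seqs = list(comp)
            freqs = np.array([comp[s] for s in seqs], dtype=float)
            freqs = freqs / freqs.sum()
            counts = rng.multinomial(cov, freqs)
            recs: list[tuple[str, str, str]] = []
            idx = 0
            for seq, cnt in zip(seqs, counts):
                if cnt == 0:
                    continue
                L = len(seq)
                clean_qual = qhigh * L
                n_err = (
                    rng.binomial(L, params.error_rate, size=cnt)
                    if params.error_rate > 0
                    else np.zeros(cnt, dtype=int)
                )
                for k in n_err:
                    rid = f"{bee}|{marker}|{idx:06d}"
                    if k == 0:
                        recs.append((rid, seq, clean_qual))
                    else:
                        pos = rng.choice(L, size=int(k), replace=False) + 1
                        bases = _mutate(seq, pos, rng)
                        qual = list(clean_qual)
                        for p in pos:
                            qual[p - 1] = qlow
                        recs.append((rid, bases, "".join(qual)))
                    idx += 1
            order = rng.permutation(len(recs))
            reads[(bee, marker)] = [recs[i] for i in order]

    metadata = pd.DataFrame(
        {"sample_id": truth.bees, "location": [truth.bee_locations[b] for b in truth.bees]}
    )
    result = ReadSimResult(truth=truth, params=params, reads=reads, metadata=metadata)
    if out_dir is not None:
        result.write(out_dir)
    return result
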