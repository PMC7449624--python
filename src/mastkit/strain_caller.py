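"""From merged amplicon reads to a per-sample strain frequency table.

The calling model is deliberately simple, matching how deep single-fragment
amplicon data is treated in strain-typing studies: discard reads whose mean
Phred quality is below 30, keep only reads whose gap-free alignment spans
the full reference (merged amplicons are fixed-length, so an exact-length
check stands in for "no gaps"), pool identical haplotypes per sample, and
admit a haplotype to the strain registry iff it exceeds 1% frequency in at
least one sample.  Two strains are distinct iff their haplotypes differ at
one or more positions.
"""

from __future__ import annotations

import warnings
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import MarkerReference, read_references, write_references


@dataclass(frozen=True, eq=False)
class QualityRead:
    """One merged read: bases plus per-base Phred scores."""

    read_id: str
    bases: str
    quals: np.ndarray  # integer Phred scores, same length as bases

    def __post_init__(self) -> None:
        quals = np.asarray(self.quals, dtype=int)
        object.__setattr__(self, "quals", quals)
        if len(self.bases) != len(quals):
            raise ValueError(f"read {self.read_id!r}: bases/quals length mismatch")
        if quals.size and (quals.min() < 0 or quals.max() > 60):
            raise ValueError(f"read {self.read_id!r}: Phred scores outside [0, 60]")

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.quals)) if self.quals.size else 0.0


@dataclass(frozen=True)
class CallerParams:
    """Quality and frequency thresholds for strain calling."""

    min_mean_phred: float = 30.0
    freq_threshold: float = 0.01
    allow_n: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.freq_threshold < 1.0:
            raise ValueError(f"freq_threshold must be in (0, 1), got {self.freq_threshold}")
        if self.min_mean_phred < 0:
            raise ValueError("min_mean_phred must be >= 0")


def reads_at_threshold(total_reads: float, freq_threshold: float = 0.01) -> float:
    """Read support corresponding to the calling threshold at a given depth."""
    return total_reads * freq_threshold


@dataclass(frozen=True)
class Strain:
    """A distinct full-length amplicon haplotype for one marker."""

    marker: str
    strain_id: str
    sequence: str
    snps: frozenset[tuple[int, str]]  # (1-based position, alternative base)

    @classmethod
    def from_haplotype(
        cls, marker: str, strain_id: str, haplotype: str, reference: MarkerReference
    ) -> "Strain":
        if len(haplotype) != len(reference):
            raise ValueError("haplotype length differs from reference")
        snps = frozenset(
            (i + 1, b)
            for i, (a, b) in enumerate(zip(reference.sequence, haplotype))
            if a != b
        )
        return cls(marker=marker, strain_id=strain_id, sequence=haplotype, snps=snps)


def snp_distance(a: Strain | str, b: Strain | str) -> int:
    """Hamming distance between two haplotypes of the same marker."""
    if isinstance(a, Strain) and isinstance(b, Strain) and a.marker != b.marker:
        raise ValueError(f"cannot compare strains of markers {a.marker!r} and {b.marker!r}")
    sa = a.sequence if isinstance(a, Strain) else a
    sb = b.sequence if isinstance(b, Strain) else b
    if len(sa) != len(sb):
        raise ValueError("haplotypes have different lengths")
    return sum(x != y for x, y in zip(sa, sb))


def parse_fastq(path: str | Path) -> list[QualityRead]:
    """Read a Phred+33 FASTQ file into QualityRead records."""
    out = []
    path = Path(path)
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            out.append(
                QualityRead(
                    rec.id,
                    str(rec.seq).upper(),
                    np.asarray(rec.letter_annotations["phred_quality"], dtype=int),
                )
            )
    except ValueError as exc:  # malformed record: add file context
        raise ValueError(f"{path}: malformed FASTQ record ({exc})") from exc
    return out


def filter_reads(
    reads: Iterable[QualityRead], params: CallerParams = CallerParams()
) -> tuple[list[QualityRead], int]:
    """Retain reads with mean Phred >= threshold (and no N by default).

    A read whose mean quality is exactly the threshold is retained; only a
    strictly lower mean is discarded.
    """
    kept: list[QualityRead] = []
    discarded = 0
    for read in reads:
        if (not params.allow_n and "N" in read.bases) or (
            read.mean_quality < params.min_mean_phred
        ):
            discarded += 1
        else:
            kept.append(read)
    return kept, discarded


def align_read(read: QualityRead | str, reference: MarkerReference) -> str | None:
    """Ungapped end-to-end placement: accept iff lengths match.

    Merged amplicons are fixed-length, so any indel changes the read length;
    a length mismatch therefore means the read could only align with gaps
    and is rejected (``None``).  Accepted reads return their base string as
    the haplotype; no mismatch limit is imposed.
    """
    bases = read.bases if isinstance(read, QualityRead) else read
    return bases if len(bases) == len(reference) else None


@dataclass
class StrainTable:
    """Per (sample, marker) strain read counts and frequencies.

    counts:
        DataFrame indexed by (marker, strain_id), columns sample ids;
        registry strains only.
    totals:
        DataFrame markers x samples of retained aligned reads; NaN marks a
        sample with no data for the marker (the "NA" bookkeeping of the
        study design this mirrors).
    registry:
        strain_id -> Strain for every called strain.
    """

    counts: pd.DataFrame
    totals: pd.DataFrame
    registry: dict[str, Strain]
    params: CallerParams = field(default_factory=CallerParams)
    references: dict[str, MarkerReference] | None = None

    @property
    def markers(self) -> list[str]:
        return list(self.totals.index)

    @property
    def samples(self) -> list[str]:
        return list(self.totals.columns)

    def frequencies(self) -> pd.DataFrame:
        """Per-sample frequency of each registry strain (NaN where no data)."""
        if self.counts.empty:
            return self.counts.astype(float)
        den = self.totals.reindex(self.counts.index.get_level_values(0))
        den.index = self.counts.index
        return self.counts / den

    def presence(self, marker: str | None = None) -> pd.DataFrame:
        """Boolean strain-by-sample matrix: frequency strictly above threshold."""
        pres = self.frequencies().gt(self.params.freq_threshold).fillna(False)
        if marker is not None:
            pres = pres.loc[marker]
        return pres

    def strains(self, marker: str | None = None) -> list[Strain]:
        if marker is None:
            return [self.registry[sid] for _, sid in self.counts.index]
        if marker not in self.counts.index.get_level_values(0):
            return []
        return [self.registry[sid] for sid in self.counts.loc[marker].index]

    def marker_samples(self, marker: str) -> list[str]:
        """Samples with data (non-missing) for a marker."""
        row = self.totals.loc[marker]
        return list(row.index[row.notna()])

    # -- persistence ------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.rename_axis(["marker", "strain_id"]).to_csv(
            out / "strain_counts.tsv", sep="\t"
        )
        freq = self.frequencies()
        freq.rename_axis(["marker", "strain_id"]).to_csv(
            out / "strain_frequencies.tsv", sep="\t", float_format="%.10g"
        )
        self.presence().rename_axis(["marker", "strain_id"]).astype(int).to_csv(
            out / "strain_presence.tsv", sep="\t"
        )
        self.totals.rename_axis("marker").to_csv(out / "read_totals.tsv", sep="\t")
        records = [
            SeqRecord(Seq(s.sequence), id=sid, description=f"marker={s.marker}")
            for sid, s in self.registry.items()
        ]
        SeqIO.write(records, out / "strain_registry.fasta", "fasta")
        if self.references:
            write_references(
                self.references, out / "references.fasta", out / "frame_offsets.tsv"
            )

    @classmethod
    def load(cls, out_dir: str | Path, params: CallerParams = CallerParams()) -> "StrainTable":
        out = Path(out_dir)
        counts = pd.read_csv(out / "strain_counts.tsv", sep="\t", index_col=[0, 1])
        totals = pd.read_csv(out / "read_totals.tsv", sep="\t", index_col=0)
        references = None
        ref_fa = out / "references.fasta"
        if ref_fa.exists():
            references = read_references(ref_fa, out / "frame_offsets.tsv")
        registry: dict[str, Strain] = {}
        for rec in SeqIO.parse(str(out / "strain_registry.fasta"), "fasta"):
            marker = rec.description.split("marker=", 1)[1].split()[0]
            seq = str(rec.seq).upper()
            if references and marker in references:
                registry[rec.id] = Strain.from_haplotype(marker, rec.id, seq, references[marker])
            else:
                registry[rec.id] = Strain(marker, rec.id, seq, frozenset())
        return cls(counts=counts, totals=totals, registry=registry, params=params,
                   references=references)

    @classmethod
    def from_presence(
        cls,
        presence: pd.DataFrame,
        marker: str,
        params: CallerParams = CallerParams(),
        depth: int = 10_000,
    ) -> "StrainTable":
        """Build a minimal table from a boolean strain-by-sample matrix.

        Present strains are given identical synthetic read support well above
        the threshold; useful for permutation analyses that only consume
        presence/absence.  Registry strains carry placeholder sequences.
        """
        frac = max(2 * params.freq_threshold, 1.0 / depth)
        counts = (presence.astype(int) * int(depth * frac)).copy()
        counts.index = pd.MultiIndex.from_product([[marker], presence.index])
        totals = pd.DataFrame(
            [[float(depth)] * presence.shape[1]], index=[marker], columns=presence.columns
        )
        registry = {
            sid: Strain(marker, sid, "", frozenset()) for sid in presence.index
        }
        return cls(counts=counts, totals=totals, registry=registry, params=params)


def call_strains(
    pools: Mapping[tuple[str, str], Sequence[str]],
    references: Mapping[str, MarkerReference],
    params: CallerParams = CallerParams(),
    samples: Sequence[str] | None = None,
) -> StrainTable:
    """Pool identical haplotypes per (sample, marker) and build the registry.

    ``pools`` maps (sample_id, marker) to the retained, aligned haplotype
    strings of that sample.  A haplotype enters the global registry iff its
    frequency exceeds ``freq_threshold`` in at least one sample; registry
    strains are then reported in every sample with their raw counts, and
    presence/absence applies the strict threshold per sample.  Samples
    listed in ``samples`` but absent from ``pools`` are carried as missing.
    """
    if not pools:
        warnings.warn("call_strains: empty input, returning empty table")
    sample_ids = sorted({s for s, _ in pools})
    if samples is not None:
        sample_ids = sorted(set(sample_ids) | set(samples))
    markers = [m for m in references if any(k[1] == m for k in pools)] or list(references)

    counters: dict[tuple[str, str], Counter] = {}
    totals = pd.DataFrame(np.nan, index=markers, columns=sample_ids, dtype=float)
    for (sample, marker), haps in pools.items():
        if marker not in references:
            raise KeyError(f"no reference for marker {marker!r}")
        ctr = Counter(haps)
        bad = [h for h in ctr if len(h) != len(references[marker])]
        if bad:
            raise ValueError(
                f"unaligned haplotype length in pool ({sample}, {marker}); "
                "run align_read first"
            )
        counters[(sample, marker)] = ctr
        totals.loc[marker, sample] = sum(ctr.values())

    # Registry: haplotypes above threshold in >= 1 sample, per marker.
    registry: dict[str, Strain] = {}
    index: list[tuple[str, str]] = []
    rows: list[list[float]] = []
    for marker in markers:
        candidates: dict[str, int] = {}
        for sample in sample_ids:
            ctr = counters.get((sample, marker))
            if not ctr:
                continue
            total = sum(ctr.values())
            for hap, cnt in ctr.items():
                if cnt / total > params.freq_threshold:
                    candidates[hap] = 0
        for hap in candidates:
            candidates[hap] = sum(
                counters.get((s, marker), Counter()).get(hap, 0) for s in sample_ids
            )
        ordered = sorted(candidates, key=lambda h: (-candidates[h], h))
        for rank, hap in enumerate(ordered):
            sid = f"{marker}.s{rank:04d}"
            registry[sid] = Strain.from_haplotype(marker, sid, hap, references[marker])
            index.append((marker, sid))
            rows.append(
                [float(counters.get((s, marker), Counter()).get(hap, 0)) for s in sample_ids]
            )

    counts = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["marker", "strain_id"])
        if index
        else pd.MultiIndex.from_arrays([[], []], names=["marker", "strain_id"]),
        columns=sample_ids,
    )
    return StrainTable(
        counts=counts,
        totals=totals,
        registry=registry,
        params=params,
        references=dict(references),
    )


def pools_from_reads(
    reads: Mapping[tuple[str, str], Iterable[QualityRead]],
    references: Mapping[str, MarkerReference],
    params: CallerParams = CallerParams(),
) -> tuple[dict[tuple[str, str], list[str]], pd.DataFrame]:
    """Quality-filter and align raw reads into per-sample haplotype pools.

    Returns the pools plus an accounting table (raw / low-quality /
    unaligned / retained) per (sample, marker).
    """
    pools: dict[tuple[str, str], list[str]] = {}
    acct_rows = []
    for (sample, marker), rds in reads.items():
        rds = list(rds)
        kept, n_lowq = filter_reads(rds, params)
        haps = []
        n_gap = 0
        for r in kept:
            hap = align_read(r, references[marker])
            if hap is None:
                n_gap += 1
            else:
                haps.append(hap)
        pools[(sample, marker)] = haps
        acct_rows.append((sample, marker, len(rds), n_lowq, n_gap, len(haps)))
    accounting = pd.DataFrame(
        acct_rows,
        columns=["sample_id", "marker", "raw", "low_quality", "unaligned", "retained"],
    )
    return pools, accounting


def call_from_fastq_dir(
    reads_dir: str | Path,
    references: Mapping[str, MarkerReference],
    metadata: pd.DataFrame | None = None,
    params: CallerParams = CallerParams(),
) -> tuple[StrainTable, dict[tuple[str, str], list[str]], pd.DataFrame]:
    """Call strains from a directory of ``<sample>_<marker>.fastq`` files.

    Returns (table, raw read pools for relaxed re-search, accounting table).
    """
    reads_dir = Path(reads_dir)
    raw: dict[tuple[str, str], list[QualityRead]] = {}
    for path in sorted(reads_dir.glob("*.fastq")):
        stem = path.stem
        sample, _, marker = stem.rpartition("_")
        if marker not in references:
            warnings.warn(f"skipping {path.name}: unknown marker {marker!r}")
            continue
        raw[(sample, marker)] = parse_fastq(path)
    pools, accounting = pools_from_reads(raw, references, params)
    samples = list(metadata["sample_id"]) if metadata is not None else None
    table = call_strains(pools, references, params, samples=samples)
    raw_pools = {key: [r.bases for r in rds] for key, rds in raw.items()}
    return table, raw_pools, accounting


def rescue_cryptic(
    table: StrainTable,
    raw_pools: Mapping[tuple[str, str], Iterable[str]],
) -> pd.DataFrame:
    """Relaxed single-read re-search of registry strains in the full read pool.

    For every called strain, ``strict_prevalence`` is the fraction of
    samples where it passed the frequency threshold and
    ``relaxed_prevalence`` the fraction where its exact haplotype is
    supported by at least one read anywhere in the sample's unfiltered
    pool (quality-filtered and sub-threshold reads included).
    ``fold_change`` = relaxed / strict (infinite when strict is 0).
    """
    if not table.registry:
        raise ValueError("rescue_cryptic: empty strain registry")
    pres = table.presence()
    pool_sets: dict[tuple[str, str], set[str]] = {
        key: set(reads) for key, reads in raw_pools.items()
    }
    rows = []
    for (marker, sid) in table.counts.index:
        strain = table.registry[sid]
        samples = table.marker_samples(marker)
        if not samples:
            continue
        strict_n = int(pres.loc[(marker, sid), samples].sum())
        relaxed_n = sum(
            1 for s in samples if strain.sequence in pool_sets.get((s, marker), ())
        )
        strict = strict_n / len(samples)
        relaxed = relaxed_n / len(samples)
        fold = relaxed / strict if strict > 0 else float("inf")
        rows.append((marker, sid, strict, relaxed, fold))
    return pd.DataFrame(
        rows,
        columns=["marker", "strain_id", "strict_prevalence", "relaxed_prevalence", "fold_change"],
    ).set_index("strain_id")
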