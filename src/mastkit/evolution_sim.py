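"""In-silico marker-sequence evolution with codon-position-aware SNP placement.

Two experiments, both arguing from the absence of sequence convergence:

* PCR-artifact mode — every strain sequence in every host is generated
  independently from the marker reference by a Poisson number of SNPs
  placed uniformly along the sequence.  If independently generated
  sequences essentially never coincide across hosts, PCR errors cannot
  explain identical strains being observed in many hosts.
* purifying-selection mode — the same, but SNP sites are drawn with
  empirical codon-position weights (third position most free, second most
  constrained), testing whether selective constraint could funnel
  independent mutations into identical haplotypes.

The study design emulated here simulates 144 hosts with 6 strains each for
three markers and 16 for the fourth, yielding ~5,000 sequences in total.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np

from .strain_caller import Strain
from .synthetic_data import ALPHABET, MarkerReference, default_references

#: Strains simulated per host for each default marker.
DEFAULT_STRAINS_PER_BEE: dict[str, int] = {"guaA": 6, "gluS": 6, "rimM": 6, "pflA": 16}

#: Poisson mean SNPs per simulated strain (mean pairwise SNP distance
#: observed among strains sharing a host: ~8 for the species-level markers,
#: ~20 for the genus-level rimM marker).
DEFAULT_MEAN_SNPS: dict[str, float] = {"guaA": 8.0, "gluS": 8.0, "pflA": 8.0, "rimM": 20.0}

#: Empirical codon-position substitution weights (p1, p2, p3) per marker.
DEFAULT_CODON_WEIGHTS: dict[str, tuple[float, float, float]] = {
    "guaA": (0.12, 0.10, 0.78),
    "gluS": (0.17, 0.04, 0.79),
    "pflA": (0.14, 0.04, 0.82),
    "rimM": (0.20, 0.09, 0.71),
}

DEFAULT_N_BEES = 144


def codon_position(position: int, frame_offset: int) -> int | None:
    """Codon position (1-3) of a 1-based site; None before the first codon."""
    if position <= frame_offset:
        return None
    return (position - frame_offset - 1) % 3 + 1


@dataclass(frozen=True)
class SimulationConfig:
    """One marker's evolution-simulation settings.

    ``codon_weights`` of None means uniform placement (PCR-artifact mode);
    a (p1, p2, p3) triple summing to 1 selects purifying-selection mode.
    """

    reference: MarkerReference
    n_bees: int = DEFAULT_N_BEES
    strains_per_bee: int = 6
    mean_snps: float = 8.0
    codon_weights: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bees < 1:
            raise ValueError("n_bees must be >= 1")
        if self.strains_per_bee < 1:
            raise ValueError("strains_per_bee must be >= 1")
        if self.mean_snps < 0:
            raise ValueError("mean_snps must be >= 0")
        if self.mean_snps > len(self.reference):
            raise ValueError("mean_snps exceeds the reference length")
        if self.codon_weights is not None:
            w = np.asarray(self.codon_weights, dtype=float)
            if w.shape != (3,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("codon_weights must be 3 non-negative values summing to 1")


@dataclass
class SimulatedStrainSets:
    """Per-bee simulated sequences plus the SNPs applied to each."""

    config: SimulationConfig
    sequences: list[list[str]]  # [bee][strain]
    provenance: list[list[list[tuple[int, str]]]]  # applied (position, alt) per sequence

    @property
    def n_sequences(self) -> int:
        return sum(len(s) for s in self.sequences)

    def distinct_sequences(self) -> set[str]:
        return {s for bee in self.sequences for s in bee}


def estimate_codon_weights(
    registry: Iterable[Strain], reference: MarkerReference
) -> tuple[float, float, float]:
    """Empirical codon-position fractions of the distinct SNPs in a registry.

    Counts each distinct (position, alternative base) once across all
    strains of the reference's marker; sites preceding the first complete
    codon are excluded.
    """
    snps: set[tuple[int, str]] = set()
    for strain in registry:
        if strain.marker != reference.name:
            continue
        snps.update(strain.snps)
    counts = np.zeros(3)
    for pos, _alt in snps:
        cp = codon_position(pos, reference.frame_offset)
        if cp is not None:
            counts[cp - 1] += 1
    if counts.sum() == 0:
        raise ValueError("no SNPs in the registry; cannot estimate codon weights")
    w = counts / counts.sum()
    return (float(w[0]), float(w[1]), float(w[2]))


def _site_classes(reference: MarkerReference) -> list[np.ndarray]:
    """1-based positions of each codon class (sites before frame excluded)."""
    classes: list[list[int]] = [[], [], []]
    for pos in range(1, len(reference) + 1):
        cp = codon_position(pos, reference.frame_offset)
        if cp is not None:
            classes[cp - 1].append(pos)
    return [np.array(c, dtype=int) for c in classes]


def _draw_positions_weighted(
    classes: list[np.ndarray],
    weights: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> list[int]:
    """Draw k distinct sites: codon class by weight, then uniform site in class."""
    remaining = [list(c) for c in classes]
    out: list[int] = []
    w = weights.copy()
    for _ in range(k):
        avail = np.array([len(r) > 0 for r in remaining])
        if not avail.any():
            break
        p = np.where(avail, w, 0.0)
        if p.sum() == 0:
            p = avail.astype(float)
        p = p / p.sum()
        cls = int(rng.choice(3, p=p))
        j = int(rng.integers(0, len(remaining[cls])))
        out.append(remaining[cls].pop(j))
    return out


def simulate_strain_set(config: SimulationConfig) -> SimulatedStrainSets:
    """Generate every bee's strain set from the reference by Poisson SNPs.

    Each sequence draws k ~ Poisson(mean_snps) distinct sites — uniformly
    along the sequence, or codon-position-weighted in selection mode — and
    substitutes each with a uniform choice among the three alternative
    bases.  Sites within one sequence are drawn without replacement (no
    back-mutation).  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    ref = config.reference
    L = len(ref)
    classes = _site_classes(ref) if config.codon_weights is not None else None
    weights = (
        np.asarray(config.codon_weights, dtype=float)
        if config.codon_weights is not None
        else None
    )
    ref_chars = list(ref.sequence)

    sequences: list[list[str]] = []
    provenance: list[list[list[tuple[int, str]]]] = []
    for _bee in range(config.n_bees):
        bee_seqs: list[str] = []
        bee_prov: list[list[tuple[int, str]]] = []
        for _s in range(config.strains_per_bee):
            k = int(min(rng.poisson(config.mean_snps), L))
            if k == 0:
                bee_seqs.append(ref.sequence)
                bee_prov.append([])
                continue
            if weights is None:
                positions = list(rng.choice(L, size=k, replace=False) + 1)
            else:
                positions = _draw_positions_weighted(classes, weights, k, rng)
            chars = ref_chars.copy()
            applied: list[tuple[int, str]] = []
            for pos in positions:
                old = chars[pos - 1]
                alternatives = [b for b in ALPHABET if b != old]
                alt = alternatives[rng.integers(0, 3)]
                chars[pos - 1] = alt
                applied.append((int(pos), alt))
            bee_seqs.append("".join(chars))
            bee_prov.append(applied)
        sequences.append(bee_seqs)
        provenance.append(bee_prov)
    return SimulatedStrainSets(config=config, sequences=sequences, provenance=provenance)


def count_convergence(sets: SimulatedStrainSets) -> int:
    """Distinct non-reference sequences independently generated in >= 2 bees."""
    if len(sets.sequences) < 2:
        raise ValueError("convergence requires at least two bees")
    ref_seq = sets.config.reference.sequence
    carriers: dict[str, set[int]] = {}
    for bee_idx, bee_seqs in enumerate(sets.sequences):
        for seq in bee_seqs:
            if seq == ref_seq:
                continue
            carriers.setdefault(seq, set()).add(bee_idx)
    return sum(1 for bees in carriers.values() if len(bees) >= 2)


def count_within_bee_duplicates(sets: SimulatedStrainSets) -> int:
    """Distinct non-reference sequences generated more than once in one bee."""
    ref_seq = sets.config.reference.sequence
    dup = 0
    for bee_seqs in sets.sequences:
        seen: dict[str, int] = {}
        for seq in bee_seqs:
            if seq == ref_seq:
                continue
            seen[seq] = seen.get(seq, 0) + 1
        dup += sum(1 for c in seen.values() if c > 1)
    return dup


@dataclass
class EvolutionExperiment:
    """Pooled result of running the simulation over several markers."""

    per_marker: dict[str, SimulatedStrainSets]

    @property
    def total_sequences(self) -> int:
        return sum(s.n_sequences for s in self.per_marker.values())

    @property
    def distinct_sequences(self) -> int:
        return sum(len(s.distinct_sequences()) for s in self.per_marker.values())

    @property
    def convergent_sequences(self) -> int:
        return sum(count_convergence(s) for s in self.per_marker.values())

    def summary(self) -> dict:
        return {
            "total_sequences": self.total_sequences,
            "distinct_sequences": self.distinct_sequences,
            "convergent_sequences": self.convergent_sequences,
            "markers": {
                m: {
                    "n_sequences": s.n_sequences,
                    "distinct": len(s.distinct_sequences()),
                    "convergent": count_convergence(s),
                }
                for m, s in self.per_marker.items()
            },
        }


def run_evolution_experiment(
    mode: str = "pcr",
    references: Mapping[str, MarkerReference] | None = None,
    n_bees: int = DEFAULT_N_BEES,
    strains_per_bee: Mapping[str, int] | None = None,
    mean_snps: Mapping[str, float] | None = None,
    codon_weights: Mapping[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
) -> EvolutionExperiment:
    """Run the full multi-marker experiment in ``"pcr"`` or ``"selection"`` mode."""
    if mode not in ("pcr", "selection"):
        raise ValueError(f"mode must be 'pcr' or 'selection', got {mode!r}")
    references = dict(references) if references else default_references(seed=seed)
    strains_per_bee = dict(strains_per_bee or DEFAULT_STRAINS_PER_BEE)
    mean_snps = dict(mean_snps or DEFAULT_MEAN_SNPS)
    codon_weights = dict(codon_weights or DEFAULT_CODON_WEIGHTS)
    rng = np.random.default_rng(seed)
    per_marker = {}
    for marker, ref in references.items():
        config = SimulationConfig(
            reference=ref,
            n_bees=n_bees,
            strains_per_bee=int(strains_per_bee[marker]),
            mean_snps=float(mean_snps[marker]),
            codon_weights=codon_weights[marker] if mode == "selection" else None,
            seed=int(rng.integers(0, 2**31)),
        )
        per_marker[marker] = simulate_strain_set(config)
    return EvolutionExperiment(per_marker=per_marker)
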