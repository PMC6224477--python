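"""Nuclease digestion of polysome snapshots into protected fragment classes.

Each ribosome shields a ~30-nt window of mRNA around its P site.  When two
ribosomes sit at the collided footprint their protected windows abut with
no exposed linker, so nuclease cannot cut between them and the pair
survives digestion as a single disome-sized fragment; loosely spaced
polysomes collapse to monosome footprints.  Classifying merged fragments by
the number of ribosomes they span reproduces the monosome/disome/trisome
ladder seen on sucrose gradients after digestion, which is the readout used
to distinguish stochastically arrested (collision-rich) from globally
arrested (collision-free) translation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import ParameterError
from .polysome_sim import PolysomeSnapshot

__all__ = [
    "FootprintSpec",
    "FragmentProfile",
    "protected_interval",
    "digest_snapshot",
    "multimer_distribution",
]


@dataclass(frozen=True)
class FootprintSpec:
    """Nucleotide-level protection geometry of one ribosome.

    The ribosome protects ``codons_upstream_of_p`` codons 5' of the P-site
    codon and ``codons_downstream_of_p`` codons 3' of it (defaults 4 + 1 + 5
    = 10 codons = 30 nt, chosen so that neighbours at the 10-codon collided
    gap abut exactly).  An exposed linker shorter than
    ``min_cuttable_linker_nt`` cannot be cut and merges the flanking
    protections.
    """

    codons_upstream_of_p: int = 4
    codons_downstream_of_p: int = 5
    min_cuttable_linker_nt: int = 3

    def __post_init__(self) -> None:
        if self.codons_upstream_of_p < 0 or self.codons_downstream_of_p < 0:
            raise ParameterError("protected codon counts must be >= 0")
        if self.min_cuttable_linker_nt < 1:
            raise ParameterError("min_cuttable_linker_nt must be >= 1")

    @property
    def protected_codons(self) -> int:
        return self.codons_upstream_of_p + 1 + self.codons_downstream_of_p

    @property
    def protected_nt(self) -> int:
        return 3 * self.protected_codons


@dataclass(frozen=True)
class FragmentProfile:
    """Digestion products: one (ribosomes spanned, length in nt) pair per
    surviving fragment."""

    fragments: tuple[tuple[int, int], ...]
    total_ribosomes: int

    def __post_init__(self) -> None:
        if sum(n for n, _ in self.fragments) != self.total_ribosomes:
            raise ParameterError("fragment ribosome counts do not sum to the total")
        if any(length <= 0 for _, length in self.fragments):
            raise ParameterError("fragment lengths must be > 0")

    @property
    def class_counts(self) -> dict[int, int]:
        return dict(Counter(n for n, _ in self.fragments))

    @property
    def fragment_lengths_nt(self) -> list[int]:
        return [length for _, length in self.fragments]

    def ribosome_fraction(self, min_size: int = 2) -> float:
        """Fraction of ribosomes residing in fragments of >= ``min_size``
        ribosomes (0.0 for an empty profile)."""
        if self.total_ribosomes == 0:
            return 0.0
        return sum(n for n, _ in self.fragments if n >= min_size) / self.total_ribosomes


def protected_interval(
    p_site: int, spec: FootprintSpec, transcript_length_codons: int | None = None
) -> tuple[int, int]:
    """1-based nt interval protected by a ribosome at codon ``p_site``
    (codon c spans nt 3c-2 .. 3c), clipped at transcript ends."""
    start = 3 * (p_site - spec.codons_upstream_of_p) - 2
    end = 3 * (p_site + spec.codons_downstream_of_p)
    start = max(start, 1)
    if transcript_length_codons is not None:
        end = min(end, 3 * transcript_length_codons)
    return start, end


def digest_snapshot(
    snapshot: PolysomeSnapshot,
    spec: FootprintSpec = FootprintSpec(),
    transcript_length_codons: int | None = None,
) -> FragmentProfile:
    """Digest one snapshot into nuclease-protected fragments.

    Protections are laid down 5'->3'; neighbouring protections whose
    exposed linker is shorter than ``min_cuttable_linker_nt`` merge into a
    single fragment spanning both ribosomes.  An empty snapshot gives an
    empty profile.
    """
    positions = sorted(r.p_site for r in snapshot.ribosomes)
    fragments: list[tuple[int, int, int]] = []  # (start, end, n_ribosomes)
    for p in positions:
        start, end = protected_interval(p, spec, transcript_length_codons)
        if fragments and start - fragments[-1][1] - 1 < spec.min_cuttable_linker_nt:
            s, e, n = fragments[-1]
            fragments[-1] = (s, max(e, end), n + 1)
        else:
            fragments.append((start, end, 1))
    return FragmentProfile(
        fragments=tuple((n, e - s + 1) for s, e, n in fragments),
        total_ribosomes=len(positions),
    )


def multimer_distribution(
    trajectory: list[PolysomeSnapshot],
    time: float,
    spec: FootprintSpec = FootprintSpec(),
    transcript_length_codons: int | None = None,
    normalize_to_monosome: bool = False,
) -> dict[int, float]:
    """Fragment-class counts from the latest snapshot at or before ``time``.

    With ``normalize_to_monosome`` counts are scaled to the monosome
    (class-1) count, mirroring gradient profiles normalised to the 80S
    peak.
    """
    if not trajectory:
        raise ParameterError("empty trajectory")
    eligible = [s for s in trajectory if s.time <= time]
    if not eligible:
        raise ParameterError(f"no snapshot at or before t={time}")
    profile = digest_snapshot(eligible[-1], spec, transcript_length_codons)
    counts = {size: float(c) for size, c in sorted(profile.class_counts.items())}
    if normalize_to_monosome:
        mono = counts.get(1, 0.0)
        if mono == 0:
            raise ParameterError("cannot normalize: no monosome fragments")
        counts = {size: c / mono for size, c in counts.items()}
    return counts
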