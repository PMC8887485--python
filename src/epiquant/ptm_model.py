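"""Mass and chemistry model of derivatized histone peptides.

The workflow modelled here is the standard bottom-up histone PTM pipeline:
free and monomethylated lysines are alkylated with heavy-isotope methyl
groups (reductive dimethylation with ¹³CD₂O / NaBD₃CN) *before* trypsin
digestion, so trypsin cleaves only after arginine (Arg-C-like specificity);
peptide N-termini are then propionylated.  Every endogenous lysine state
(unmodified, me1, me2, me3, ac) therefore maps to a distinct, predictable
adduct composition, and modification isoforms of the same peptide backbone
separate by precursor m/z — except positional isomers, which stay isobaric
at MS1 and are told apart by their b/y fragment ions.

All masses are monoisotopic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

PROTON_MASS = 1.007276
WATER_MASS = 18.0105646863

#: Monoisotopic residue masses for the 20 standard amino acids.
RESIDUE_MASS: Mapping[str, float] = {
    aa: m for aa, m in _pmass.std_aa_mass.items() if len(aa) == 1 and aa.isupper()
}

#: Endogenous lysine modification states handled by the model, in the
#: canonical enumeration order used everywhere downstream.
STATES: tuple[str, ...] = ("un", "me1", "me2", "me3", "ac")

# Net monoisotopic additions of the chemistry involved.
LIGHT_METHYL_DELTA = 14.0156500  # CH2 (methyl replacing an amine H)
HEAVY_METHYL_DELTA = 18.0378352  # 13CD3 replacing an amine H
ACETYL_DELTA = 42.0105646  # C2H2O
PROPIONYL_DELTA = 56.0262147  # C3H4O


class PtmModelError(ValueError):
    """Invalid input to the peptide mass/chemistry model."""


@dataclass(frozen=True)
class DerivatizationScheme:
    """Adduct masses plus the rule mapping lysine state -> installed heavy methyls.

    The default rule encodes heavy-isotope reductive dimethylation: a free
    lysine receives two heavy methyls, a monomethylated lysine receives one,
    and di-/tri-methylated or acetylated lysines are left untouched.

    Parameters
    ----------
    heavy_methyl_delta
        Net monoisotopic addition (Da) per methyl installed by the labeling
        chemistry (default ¹³CD₃ − H).
    light_methyl_delta
        Net addition of an endogenous methyl (CH₂).
    acetyl_delta, propionyl_delta
        Net additions of endogenous acetyl and of the N-terminal propionyl.
    heavy_installed
        Mapping endogenous state -> number of heavy methyls installed.
    """

    heavy_methyl_delta: float = HEAVY_METHYL_DELTA
    light_methyl_delta: float = LIGHT_METHYL_DELTA
    acetyl_delta: float = ACETYL_DELTA
    propionyl_delta: float = PROPIONYL_DELTA
    heavy_installed: Mapping[str, int] = field(
        default_factory=lambda: {"un": 2, "me1": 1, "me2": 0, "me3": 0, "ac": 0}
    )

    def __post_init__(self) -> None:
        for name in ("heavy_methyl_delta", "light_methyl_delta", "acetyl_delta", "propionyl_delta"):
            if getattr(self, name) <= 0:
                raise PtmModelError(f"{name} must be > 0")
        if self.heavy_methyl_delta <= self.light_methyl_delta:
            raise PtmModelError("heavy methyl delta must exceed the light methyl delta")
        unknown = set(self.heavy_installed) - set(STATES)
        if unknown:
            raise PtmModelError(f"unknown states in heavy-methyl rule: {sorted(unknown)}")
        object.__setattr__(self, "heavy_installed", dict(self.heavy_installed))

    def adduct_mass(self, state: str) -> float:
        """Total mass added at one lysine in the given endogenous state."""
        if state not in self.heavy_installed:
            raise PtmModelError(f"state {state!r} not covered by the derivatization rule")
        endogenous = {
            "un": 0.0,
            "me1": self.light_methyl_delta,
            "me2": 2 * self.light_methyl_delta,
            "me3": 3 * self.light_methyl_delta,
            "ac": self.acetyl_delta,
        }[state]
        return endogenous + self.heavy_installed[state] * self.heavy_methyl_delta


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide located on the mature protein.

    Residue numbering is 1-based inclusive and excludes the initiator
    methionine (histone community convention: H3 residue 1 is the Ala of
    ARTK...), so peptide 27-40 carries K27/K36/K37.
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    lysine_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise PtmModelError("peptide interval does not match sequence length")
        for pos in self.lysine_positions:
            if not (self.start <= pos <= self.end):
                raise PtmModelError(f"lysine position {pos} outside peptide interval")
            if self.sequence[pos - self.start] != "K":
                raise PtmModelError(f"residue at position {pos} is not lysine")

    @classmethod
    def from_sequence(cls, protein_id: str, start: int, sequence: str) -> "Peptide":
        lys = tuple(start + i for i, aa in enumerate(sequence) if aa == "K")
        return cls(protein_id, start, start + len(sequence) - 1, sequence, lys)

    @property
    def label(self) -> str:
        return f"{self.protein_id}:{self.start}-{self.end}"


@dataclass(frozen=True)
class PTMIsoform:
    """One modification isoform: an endogenous state per modifiable lysine."""

    peptide: Peptide
    states: tuple[tuple[int, str], ...]  # (lysine position, state), sorted by position

    def __post_init__(self) -> None:
        positions = tuple(p for p, _ in self.states)
        if positions != self.peptide.lysine_positions:
            raise PtmModelError("isoform must assign exactly one state to every lysine")
        for _, s in self.states:
            if s not in STATES:
                raise PtmModelError(f"unknown lysine state {s!r}")

    @property
    def label(self) -> str:
        """Human-readable state combination, e.g. ``K27me3-K36un-K37un``."""
        if not self.states:
            return "unmodified"
        return "-".join(f"K{p}{s}" for p, s in self.states)

    def state_at(self, position: int) -> str:
        return dict(self.states)[position]


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-series fragment of a derivatized isoform."""

    isoform: PTMIsoform
    series: str  # "b" or "y"
    index: int  # 1 .. len(peptide) - 1
    charge: int
    mz: float

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.series, self.index, self.charge)


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise PtmModelError("empty protein sequence")
    bad = set(sequence) - set(RESIDUE_MASS)
    if bad:
        raise PtmModelError(f"invalid residues in sequence: {sorted(bad)}")


def digest(
    protein_sequence: str,
    blocked_lysines: bool = True,
    protein_id: str = "protein",
    missed_cleavages: int = 0,
) -> list[Peptide]:
    """Digest a protein with trypsin, optionally with chemically blocked lysines.

    With ``blocked_lysines=True`` (derivatization precedes digestion) trypsin
    behaves Arg-C-like: cleavage C-terminal to R only.  Cleavage never occurs
    before a proline.  Peptides are returned in N-to-C order with 1-based
    inclusive residue intervals; optional missed cleavages concatenate up to
    ``missed_cleavages`` adjacent fragments.
    """
    _check_sequence(protein_sequence)
    if missed_cleavages < 0 or missed_cleavages > 2:
        raise PtmModelError("missed_cleavages must be between 0 and 2")
    cut_after = "R" if blocked_lysines else "KR"
    boundaries = [0]
    for i, aa in enumerate(protein_sequence[:-1]):
        if aa in cut_after and protein_sequence[i + 1] != "P":
            boundaries.append(i + 1)
    boundaries.append(len(protein_sequence))

    base: list[Peptide] = []
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        base.append(Peptide.from_sequence(protein_id, s + 1, protein_sequence[s:e]))
    if missed_cleavages == 0:
        return base
    out = list(base)
    for k in range(1, missed_cleavages + 1):
        for i in range(len(base) - k):
            seq = "".join(p.sequence for p in base[i : i + k + 1])
            out.append(Peptide.from_sequence(protein_id, base[i].start, seq))
    return sorted(out, key=lambda p: (p.start, p.end))


def enumerate_isoforms(
    peptide: Peptide,
    allowed_states: Sequence[str] = STATES,
    variable_positions: Sequence[int] | None = None,
) -> list[PTMIsoform]:
    """All state combinations over the peptide's modifiable lysines.

    Order is deterministic: the Cartesian product with states cycling in
    canonical ``STATES`` order, fastest at the C-terminal-most lysine.
    ``variable_positions`` restricts enumeration to a subset of the lysines;
    the rest are held unmodified (they still receive the heavy dimethyl on
    derivatization).
    """
    bad = set(allowed_states) - set(STATES)
    if bad:
        raise PtmModelError(f"unknown states: {sorted(bad)}")
    states = tuple(s for s in STATES if s in set(allowed_states))
    if variable_positions is None:
        variable = peptide.lysine_positions
    else:
        variable = tuple(p for p in peptide.lysine_positions if p in set(variable_positions))
        stray = set(variable_positions) - set(peptide.lysine_positions)
        if stray:
            raise PtmModelError(f"variable positions not on peptide: {sorted(stray)}")
    out = []
    for combo in itertools.product(states, repeat=len(variable)):
        assigned = dict(zip(variable, combo))
        full = tuple(
            (p, assigned.get(p, "un")) for p in peptide.lysine_positions
        )
        out.append(PTMIsoform(peptide, full))
    return out


def _residue_masses(
    isoform: PTMIsoform, scheme: DerivatizationScheme, n_term_propionyl: bool
) -> list[float]:
    """Per-residue masses with site adducts placed on their residues."""
    pep = isoform.peptide
    masses = [RESIDUE_MASS[aa] for aa in pep.sequence]
    for pos, state in isoform.states:
        masses[pos - pep.start] += scheme.adduct_mass(state)
    if n_term_propionyl:
        masses[0] += scheme.propionyl_delta
    return masses


def derivatized_mass(
    isoform: PTMIsoform,
    scheme: DerivatizationScheme,
    n_term_propionyl: bool = True,
) -> float:
    """Neutral monoisotopic mass of the fully derivatized isoform (Da)."""
    return sum(_residue_masses(isoform, scheme, n_term_propionyl)) + WATER_MASS


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of the ``charge``-protonated species."""
    if charge < 1:
        raise PtmModelError("charge must be >= 1")
    return (neutral_mass + charge * PROTON_MASS) / charge


def fragment_ions(
    isoform: PTMIsoform,
    scheme: DerivatizationScheme,
    series: str,
    charge: int = 1,
    n_term_propionyl: bool = True,
) -> list[FragmentIon]:
    """All b- or y-ions of the derivatized isoform at the given charge.

    Neutral fragment masses follow the usual convention: b_i = sum of the
    first i residue masses (adducts included), y_j = sum of the last j plus
    water; hence mass(b_i) + mass(y_{n-i}) equals the precursor neutral mass.
    """
    if series not in ("b", "y"):
        raise PtmModelError(f"unknown ion series {series!r}")
    if charge < 1:
        raise PtmModelError("charge must be >= 1")
    masses = _residue_masses(isoform, scheme, n_term_propionyl)
    n = len(masses)
    ions = []
    for i in range(1, n):
        if series == "b":
            neutral = sum(masses[:i])
        else:
            neutral = sum(masses[n - i :]) + WATER_MASS
        ions.append(FragmentIon(isoform, series, i, charge, mz(neutral, charge)))
    return ions


def ppm_diff(mz_a: float, mz_b: float) -> float:
    """Relative m/z difference in parts per million."""
    return abs(mz_a - mz_b) / mz_a * 1e6


def unique_fragments(
    iso_a: PTMIsoform,
    iso_b: PTMIsoform,
    scheme: DerivatizationScheme,
    tolerance_ppm: float = 10.0,
    charge: int = 1,
) -> tuple[list[FragmentIon], list[FragmentIon]]:
    """Fragments distinguishing two isoforms of the same backbone.

    b/y ions are paired by series and index; a pair whose m/z differ by more
    than ``tolerance_ppm`` contributes one distinguishing ion to each side.
    """
    if iso_a.peptide != iso_b.peptide:
        raise PtmModelError("isoforms must share the same peptide backbone")
    only_a, only_b = [], []
    for series in ("b", "y"):
        for fa, fb in zip(
            fragment_ions(iso_a, scheme, series, charge),
            fragment_ions(iso_b, scheme, series, charge),
        ):
            if ppm_diff(fa.mz, fb.mz) > tolerance_ppm:
                only_a.append(fa)
                only_b.append(fb)
    return only_a, only_b


def validate_tolerance(
    scheme: DerivatizationScheme,
    precursor_mz: float,
    tolerance_ppm: float,
) -> None:
    """Reject an MS1 tolerance too coarse for the me3-vs-acetyl mass gap.

    Endogenous trimethyl and acetyl differ by only 3x(light methyl) - acetyl
    (~0.0364 Da); the matching tolerance must resolve that gap at the
    quantified precursor m/z or the two states collapse.
    """
    gap = abs(3 * scheme.light_methyl_delta - scheme.acetyl_delta)
    gap_ppm = gap / precursor_mz * 1e6
    if tolerance_ppm >= gap_ppm:
        raise PtmModelError(
            f"tolerance {tolerance_ppm} ppm cannot resolve the me3/ac gap "
            f"({gap_ppm:.1f} ppm at m/z {precursor_mz:.2f})"
        )


def theoretical_isoforms(
    peptides: Iterable[Peptide],
    allowed_states: Sequence[str] = STATES,
    variable_positions: Mapping[str, Sequence[int]] | None = None,
) -> list[PTMIsoform]:
    """Isoform catalogue over several peptides (convenience for matching).

    ``variable_positions`` optionally maps a peptide label to the subset of
    its lysines enumerated as variable.
    """
    out: list[PTMIsoform] = []
    for pep in peptides:
        var = variable_positions.get(pep.label) if variable_positions else None
        out.extend(enumerate_isoforms(pep, allowed_states, var))
    return out


def load_h3_sequence() -> str:
    """Canonical mature human H3 sequence shipped with the package."""
    from importlib.resources import files

    text = files("epiquant").joinpath("data/H3.fasta").read_text()
    return "".join(
        line.strip() for line in text.splitlines() if not line.startswith(">")
    )


def h3_isoform_catalogue() -> list[PTMIsoform]:
    """Default quantified isoform catalogue for the H3 tail peptides.

    Enumerates the routinely quantified lysines (K4, K9/K14, K18/K23,
    K27/K36) over all five states; K37 is held unmodified.  Restricting the
    27-40 peptide to two variable sites keeps every isobaric group
    resolvable: within such a group each member carries a distinct K27
    state, so b-ions N-terminal to K36 are always distinguishing.
    """
    peptides = [
        p for p in digest(load_h3_sequence(), protein_id="H3") if p.lysine_positions
    ]
    variable = {"H3:27-40": (27, 36)}
    return theoretical_isoforms(peptides, variable_positions=variable)
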