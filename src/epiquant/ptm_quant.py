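"""Relative quantification of histone PTMs from XIC peaks and MS2 spectra.

The quantification convention: for each histone peptide, the summed
extracted-ion-chromatogram (XIC) areas of all its modification isoforms are
taken as 100 %, and each isoform's percentage is its area over that total.
Only the highest-intensity charge state of each isoform group is measured.
Positional isomers that are isobaric at MS1 share one XIC peak; their shared
area is apportioned by the ratio of their unique b/y fragment intensities in
the MS2 spectrum.  Condition contrasts are reported as log base-1.5 fold
changes of the percentages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from epiquant import ptm_model
from epiquant.ptm_model import DerivatizationScheme, PTMIsoform, ppm_diff


class PtmQuantError(ValueError):
    """Invalid input to the PTM quantification stage."""


class UnresolvedIsobarsError(PtmQuantError):
    """Isobaric isoforms whose unique fragments are all absent from MS2."""


@dataclass(frozen=True)
class XicPeak:
    """An integrated MS1 chromatographic peak."""

    sample: str
    mz: float
    charge: int
    rt: float
    area: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise PtmQuantError("peak area must be >= 0")
        if self.charge < 1:
            raise PtmQuantError("charge must be >= 1")


@dataclass(frozen=True)
class Ms2Spectrum:
    """A fragment spectrum tied to a precursor."""

    precursor_mz: float
    charge: int
    rt: float
    fragments: tuple[tuple[float, float], ...]  # (m/z, intensity)

    def __post_init__(self) -> None:
        if not self.fragments:
            raise PtmQuantError("fragment list must be non-empty")
        if any(i < 0 for _, i in self.fragments):
            raise PtmQuantError("fragment intensities must be >= 0")

    def intensity_at(self, mz: float, tolerance_ppm: float) -> float:
        """Summed intensity of fragments within tolerance of ``mz``."""
        return sum(i for m, i in self.fragments if ppm_diff(mz, m) <= tolerance_ppm)


@dataclass
class AbundanceTable:
    """Per-peptide relative PTM abundances, normalized to 100 %.

    ``combinations`` holds full state-combination percentages
    (e.g. ``K27me3-K36un-K37un``); ``marginals`` holds per-site state
    percentages (e.g. ``K27me3``), obtained by summing combinations that
    share the site state.  Peptides whose areas were all zero are listed in
    ``missing`` rather than emitted as zeros.
    """

    combinations: dict[str, dict[str, float]] = field(default_factory=dict)
    marginals: dict[str, dict[str, float]] = field(default_factory=dict)
    missing: list[str] = field(default_factory=list)


@dataclass
class FoldChangeMatrix:
    """log-1.5 fold changes of condition B over condition A percentages."""

    condition_a: str
    condition_b: str
    combinations: dict[str, dict[str, float]] = field(default_factory=dict)
    marginals: dict[str, dict[str, float]] = field(default_factory=dict)


#: Default elution-order heuristic for near-isobaric state classes on a
#: C18 reversed-phase column: the dimethyl-bearing class elutes before the
#: acetyl-bearing class.  Configurable because the ordering is empirical.
DEFAULT_RT_ORDER: tuple[str, ...] = ("dimethyl", "acetyl")


def state_class(isoform: PTMIsoform) -> str | None:
    """Coarse hydrophobicity class used by the elution-order heuristic."""
    states = [s for _, s in isoform.states]
    if "ac" in states:
        return "acetyl"
    if "me2" in states:
        return "dimethyl"
    return None


def match_peaks(
    peaks: Sequence[XicPeak],
    isoforms: Sequence[PTMIsoform],
    scheme: DerivatizationScheme,
    tolerance_ppm: float = 10.0,
    rt_order: Sequence[str] | None = DEFAULT_RT_ORDER,
) -> dict[XicPeak, list[PTMIsoform]]:
    """Assign each XIC peak to candidate isoforms by m/z, then RT.

    A peak matches every isoform whose theoretical m/z at the peak's charge
    lies within ``tolerance_ppm``; isobaric positional isomers are kept
    together for downstream fragment splitting.  When a peak matches several
    *non-isobaric* candidates (near-isobaric state classes at a coarse
    tolerance) the configured elution ordering assigns earlier-eluting peaks
    of the same m/z group to earlier classes; ambiguity the ordering cannot
    resolve is carried forward, never dropped.  Peaks matching nothing map
    to an empty list ("unassigned").
    """
    neutral = [(iso, ptm_model.derivatized_mass(iso, scheme)) for iso in isoforms]
    matches: dict[XicPeak, list[PTMIsoform]] = {}
    for peak in peaks:
        cands = [
            iso
            for iso, m in neutral
            if ppm_diff(peak.mz, ptm_model.mz(m, peak.charge)) <= tolerance_ppm
        ]
        matches[peak] = _dedupe(cands)

    if rt_order:
        _resolve_by_rt(matches, scheme, tolerance_ppm, tuple(rt_order))
    return matches


def _dedupe(isoforms: Iterable[PTMIsoform]) -> list[PTMIsoform]:
    seen, out = set(), []
    for iso in isoforms:
        key = (iso.peptide.label, iso.label)
        if key not in seen:
            seen.add(key)
            out.append(iso)
    return out


def _resolve_by_rt(
    matches: dict[XicPeak, list[PTMIsoform]],
    scheme: DerivatizationScheme,
    tolerance_ppm: float,
    rt_order: tuple[str, ...],
) -> None:
    """Split shared non-isobaric candidate sets across co-matching peaks by RT."""
    ambiguous = [
        p
        for p, cands in matches.items()
        if len({round(ptm_model.derivatized_mass(c, scheme), 3) for c in cands}) > 1
    ]
    # Group ambiguous peaks that share the same candidate set.
    by_candset: dict[tuple, list[XicPeak]] = {}
    for p in ambiguous:
        key = tuple(sorted((c.peptide.label, c.label) for c in matches[p]))
        by_candset.setdefault(key, []).append(p)
    for peaks in by_candset.values():
        cands = matches[peaks[0]]
        classes = {state_class(c) for c in cands}
        ordered = [cls for cls in rt_order if cls in classes]
        if len(ordered) != len(classes) or len(ordered) != len(peaks):
            continue  # heuristic cannot resolve; carry ambiguity forward
        for peak, cls in zip(sorted(peaks, key=lambda p: p.rt), ordered):
            matches[peak] = [c for c in cands if state_class(c) == cls]


def select_quant_peak(peaks: Sequence[XicPeak]) -> XicPeak:
    """The highest-intensity charge state of one isoform group.

    Ties on area break toward the lower charge state.
    """
    if not peaks:
        raise PtmQuantError("no candidate peaks to select from")
    return max(peaks, key=lambda p: (p.area, -p.charge))


def split_isobaric(
    shared_area: float,
    spectrum: Ms2Spectrum,
    isoforms: Sequence[PTMIsoform],
    scheme: DerivatizationScheme,
    tolerance_ppm: float = 10.0,
) -> dict[str, float]:
    """Apportion a shared XIC area among co-eluting isobaric isoforms.

    For each isoform the intensities of its fragments that are unique
    against *every* other co-eluter are summed from the spectrum; the shared
    area is split proportionally.  The output areas sum to ``shared_area``
    exactly.  An isoform with no detected unique fragments while others have
    signal is assigned zero (with a warning); if no isoform has signal the
    split is unresolvable.
    """
    if shared_area < 0:
        raise PtmQuantError("shared area must be >= 0")
    if len(isoforms) == 1:
        return {isoforms[0].label: shared_area}

    weights: dict[str, float] = {}
    for iso in isoforms:
        unique_mz: set[float] = set()
        for other in isoforms:
            if other is iso:
                continue
            mine, _ = ptm_model.unique_fragments(iso, other, scheme, tolerance_ppm)
            unique_mz.update(f.mz for f in mine)
        # Keep only ions unique against all co-eluters.
        for other in isoforms:
            if other is iso:
                continue
            other_mz = [
                f.mz
                for series in ("b", "y")
                for f in ptm_model.fragment_ions(other, scheme, series)
            ]
            unique_mz = {
                m for m in unique_mz if all(ppm_diff(m, o) > tolerance_ppm for o in other_mz)
            }
        if not unique_mz:
            raise PtmQuantError(
                f"isoform {iso.label} has no fragments unique against its co-eluters"
            )
        weights[iso.label] = sum(spectrum.intensity_at(m, tolerance_ppm) for m in unique_mz)

    total = sum(weights.values())
    if total == 0:
        raise UnresolvedIsobarsError(
            "no unique fragments of any co-eluting isoform detected in the spectrum"
        )
    zero = [lab for lab, w in weights.items() if w == 0]
    if zero:
        warnings.warn(
            f"isoforms with no detected unique fragments assigned zero area: {zero}",
            stacklevel=2,
        )
    labels = list(weights)
    areas = {lab: shared_area * weights[lab] / total for lab in labels[:-1]}
    areas[labels[-1]] = shared_area - sum(areas.values())  # exact conservation
    return areas


def relative_abundance(
    areas: Mapping[str, Mapping[str, float]],
) -> AbundanceTable:
    """Percentages per peptide: each isoform area over the peptide total x 100.

    ``areas`` maps peptide label -> state-combination label -> area.  Also
    computes marginal per-site state percentages by summation.
    """
    table = AbundanceTable()
    for peptide, iso_areas in areas.items():
        if any(a < 0 for a in iso_areas.values()):
            raise PtmQuantError(f"negative area for peptide {peptide}")
        total = sum(iso_areas.values())
        if total == 0:
            table.missing.append(peptide)
            continue
        pct = {lab: 100.0 * a / total for lab, a in iso_areas.items()}
        table.combinations[peptide] = pct
        marg: dict[str, float] = {}
        for lab, p in pct.items():
            for site_state in lab.split("-"):
                marg[site_state] = marg.get(site_state, 0.0) + p
        table.marginals[peptide] = marg
    return table


def average_abundance(
    tables: Sequence[AbundanceTable],
) -> tuple[AbundanceTable, AbundanceTable]:
    """Mean and standard deviation of percentages across replicate runs.

    Percentages are computed per run first, then averaged; a peptide missing
    from any replicate is dropped from the mean with a warning.
    """
    if not tables:
        raise PtmQuantError("no replicate tables")
    mean, sd = AbundanceTable(), AbundanceTable()
    for kind in ("combinations", "marginals"):
        per_rep = [getattr(t, kind) for t in tables]
        common = set(per_rep[0]).intersection(*per_rep[1:])
        dropped = set().union(*per_rep) - common
        if dropped:
            warnings.warn(f"peptides missing in some replicates dropped: {sorted(dropped)}",
                          stacklevel=2)
        for pep in common:
            labels = per_rep[0][pep].keys()
            getattr(mean, kind)[pep] = {
                lab: float(np.mean([r[pep][lab] for r in per_rep])) for lab in labels
            }
            getattr(sd, kind)[pep] = {
                lab: float(np.std([r[pep][lab] for r in per_rep], ddof=0)) for lab in labels
            }
    return mean, sd


def fold_change(
    table_a: AbundanceTable,
    table_b: AbundanceTable,
    pseudocount: float = 0.01,
    condition_a: str = "A",
    condition_b: str = "B",
    base: float = 1.5,
) -> FoldChangeMatrix:
    """log_base(percent_B / percent_A) with a pseudocount on both sides.

    The default base 1.5 matches the heatmap convention for histone
    methylation contrasts; a ratio of 1.5 maps to 1.0, equality to 0.0, and
    at pseudocount 0 the matrix is antisymmetric under condition swap.
    Keys present in only one condition are omitted with a warning.
    """
    if pseudocount < 0:
        raise PtmQuantError("pseudocount must be >= 0")
    fc = FoldChangeMatrix(condition_a, condition_b)
    log_base = math.log(base)
    for kind in ("combinations", "marginals"):
        a_side, b_side = getattr(table_a, kind), getattr(table_b, kind)
        out = getattr(fc, kind)
        skipped = []
        for pep in a_side.keys() | b_side.keys():
            if pep not in a_side or pep not in b_side:
                skipped.append(pep)
                continue
            out[pep] = {}
            for lab in a_side[pep].keys() | b_side[pep].keys():
                if lab not in a_side[pep] or lab not in b_side[pep]:
                    skipped.append(f"{pep}/{lab}")
                    continue
                pa, pb = a_side[pep][lab], b_side[pep][lab]
                out[pep][lab] = math.log((pb + pseudocount) / (pa + pseudocount)) / log_base
        if skipped:
            warnings.warn(f"keys absent in one condition omitted: {sorted(skipped)}",
                          stacklevel=2)
    return fc


def quantify_run(
    peaks: Sequence[XicPeak],
    spectra: Sequence[Ms2Spectrum],
    isoforms: Sequence[PTMIsoform],
    scheme: DerivatizationScheme,
    tolerance_ppm: float = 10.0,
    rt_order: Sequence[str] | None = DEFAULT_RT_ORDER,
) -> AbundanceTable:
    """End-to-end per-run quantification: match, select, split, normalize."""
    if peaks:
        validate_mz = min(p.mz for p in peaks)
        ptm_model.validate_tolerance(scheme, validate_mz, tolerance_ppm)
    matches = match_peaks(peaks, isoforms, scheme, tolerance_ppm, rt_order)

    # Group matched peaks by their (peptide, candidate-set) identity so that
    # charge states of the same isoform group compete for selection.
    groups: dict[tuple, list[XicPeak]] = {}
    for peak, cands in matches.items():
        if not cands:
            continue
        key = tuple(sorted((c.peptide.label, c.label) for c in cands))
        groups.setdefault(key, []).append(peak)

    areas: dict[str, dict[str, float]] = {}
    for key, grp_peaks in groups.items():
        peak = select_quant_peak(grp_peaks)
        cands = matches[peak]
        pep_label = cands[0].peptide.label
        pep_areas = areas.setdefault(pep_label, {})
        if len(cands) == 1:
            pep_areas[cands[0].label] = pep_areas.get(cands[0].label, 0.0) + peak.area
        else:
            spectrum = _spectrum_for(peak, spectra, tolerance_ppm)
            if spectrum is None:
                raise UnresolvedIsobarsError(
                    f"no MS2 spectrum found for isobaric peak at m/z {peak.mz:.4f}"
                )
            for lab, area in split_isobaric(
                peak.area, spectrum, cands, scheme, tolerance_ppm
            ).items():
                pep_areas[lab] = pep_areas.get(lab, 0.0) + area
    return relative_abundance(areas)


def _spectrum_for(
    peak: XicPeak, spectra: Sequence[Ms2Spectrum], tolerance_ppm: float
) -> Ms2Spectrum | None:
    cands = [
        s
        for s in spectra
        if s.charge == peak.charge and ppm_diff(peak.mz, s.precursor_mz) <= tolerance_ppm
    ]
    if not cands:
        return None
    return min(cands, key=lambda s: abs(s.rt - peak.rt))
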