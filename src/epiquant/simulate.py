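"""Ground-truthed synthetic inputs for both analysis arms.

Arm 1 emulates the MS1/MS2 observables of a derivatized histone-peptide
LC-MS/MS run: one XIC peak per resolvable m/z-RT group with area
proportional to the summed true isoform abundances (multiplicative
log-normal noise), and, for groups of co-eluting isobaric isoforms, an MS2
spectrum whose fragment intensities are proportional to the co-eluters'
abundances plus a uniform additive floor.

Arm 2 emulates a two-condition spike-in ChIP experiment: per-sample binned
Poisson coverage with mean = depth x (background + enrichment inside true
domains), spike-in read counts, and "called" peaks equal to the true
domains, so the downstream interval logic is tested against known truth.

Seeds are mandatory; a fixed seed fixes every output byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from epiquant import ptm_model
from epiquant.chiprx import ChipSample, GenomicTrack
from epiquant.domains import GeneModel, Peak, PeakSet
from epiquant.ptm_model import DerivatizationScheme, PTMIsoform, Peptide, ppm_diff
from epiquant.ptm_quant import Ms2Spectrum, XicPeak


class SimulationError(ValueError):
    """Invalid ground-truth configuration."""


class UnknownPeptideError(SimulationError):
    """A state-combination label does not fit the declared peptide."""


# ---------------------------------------------------------------------------
# Arm 1: LC-MS/MS of derivatized histone peptides
# ---------------------------------------------------------------------------


def parse_state_label(label: str, peptide: Peptide) -> PTMIsoform:
    """Turn a combination label like ``K27me1-K36me2-K37un`` into an isoform."""
    states: list[tuple[int, str]] = []
    if label != "unmodified":
        for part in label.split("-"):
            if not part.startswith("K"):
                raise UnknownPeptideError(f"unknown peptide site in label {label!r}")
            for state in ptm_model.STATES:
                if part.endswith(state) and part[1 : -len(state)].isdigit():
                    states.append((int(part[1 : -len(state)]), state))
                    break
            else:
                raise UnknownPeptideError(f"unparsable site-state {part!r}")
    states.sort()
    if tuple(p for p, _ in states) != peptide.lysine_positions:
        raise UnknownPeptideError(
            f"unknown peptide: label {label!r} does not cover the lysines "
            f"{peptide.lysine_positions} of {peptide.label}"
        )
    return PTMIsoform(peptide, tuple(states))


@dataclass
class PtmGroundTruth:
    """True isoform composition of one histone peptide in one sample.

    ``abundances`` maps state-combination label -> true relative fraction
    (summing to 1); ``rts`` gives each combination's true elution apex in
    minutes — isobaric positional isomers should share an RT to co-elute.
    """

    peptide: Peptide
    abundances: Mapping[str, float]
    rts: Mapping[str, float]
    seed: int
    area_sigma: float = 0.05
    fragment_noise: float = 0.01

    def __post_init__(self) -> None:
        if self.area_sigma < 0 or self.fragment_noise < 0:
            raise SimulationError("noise parameters must be >= 0")
        if any(a < 0 for a in self.abundances.values()):
            raise SimulationError("abundances must be >= 0")
        if abs(sum(self.abundances.values()) - 1.0) > 1e-9:
            raise SimulationError("abundances must sum to 1")
        if set(self.abundances) != set(self.rts):
            raise SimulationError("abundances and RTs must cover the same isoforms")
        if any(rt <= 0 for rt in self.rts.values()):
            raise SimulationError("RT values must be positive")
        for label in self.abundances:
            parse_state_label(label, self.peptide)  # raises if inconsistent


def simulate_ptm_run(
    truth: PtmGroundTruth,
    scheme: DerivatizationScheme,
    charge: int = 2,
    tolerance_ppm: float = 10.0,
    rt_window: float = 0.5,
    scale: float = 1e6,
    sample: str = "run",
) -> tuple[list[XicPeak], list[Ms2Spectrum]]:
    """Emit XIC peaks and (for isobaric groups) MS2 spectra for one run.

    Isoforms whose precursor m/z agree within ``tolerance_ppm`` and whose
    true RTs fall within ``rt_window`` minutes share one XIC peak; the
    shared peak's MS2 spectrum carries every co-eluter's b/y ions with
    intensity proportional to its true abundance.
    """
    rng = np.random.default_rng(truth.seed)
    entries = []
    for label in sorted(truth.abundances):
        iso = parse_state_label(label, truth.peptide)
        m = ptm_model.derivatized_mass(iso, scheme)
        entries.append((ptm_model.mz(m, charge), truth.rts[label], label, iso))
    entries.sort(key=lambda e: (e[0], e[1]))

    groups: list[list[tuple[float, float, str, PTMIsoform]]] = []
    for entry in entries:
        placed = False
        for grp in groups:
            if (
                ppm_diff(grp[0][0], entry[0]) <= tolerance_ppm
                and abs(grp[0][1] - entry[1]) <= rt_window
            ):
                grp.append(entry)
                placed = True
                break
        if not placed:
            groups.append([entry])

    peaks: list[XicPeak] = []
    spectra: list[Ms2Spectrum] = []
    for grp in groups:
        total_ab = sum(truth.abundances[label] for _, _, label, _ in grp)
        noise = rng.lognormal(0.0, truth.area_sigma) if truth.area_sigma > 0 else 1.0
        weights = [truth.abundances[label] / total_ab for _, _, label, _ in grp]
        peak_mz = sum(w * e[0] for w, e in zip(weights, grp))
        peak_rt = sum(w * e[1] for w, e in zip(weights, grp))
        peaks.append(XicPeak(sample, peak_mz, charge, peak_rt, scale * total_ab * noise))
        # DDA-style acquisition: every precursor gets an MS2 spectrum; for
        # shared (isobaric) peaks the co-eluters' ions mix proportionally.
        fragments: list[tuple[float, float]] = []
        for _, _, label, iso in grp:
            intensity = 1000.0 * truth.abundances[label] / total_ab
            for series in ("b", "y"):
                for frag in ptm_model.fragment_ions(iso, scheme, series):
                    fragments.append((frag.mz, intensity))
        if truth.fragment_noise > 0:
            floor = truth.fragment_noise * max(i for _, i in fragments)
            fragments = [(m, i + rng.uniform(0.0, floor)) for m, i in fragments]
        spectra.append(Ms2Spectrum(peak_mz, charge, peak_rt, tuple(fragments)))
    return peaks, spectra


def demo_ptm_truth(seed: int, area_sigma: float = 0.05,
                   fragment_noise: float = 0.01) -> PtmGroundTruth:
    """A realistic composition of the H3 27-40 peptide (K27/K36/K37).

    Includes the classic isobaric positional-isomer pair
    K27me1·K36me2 / K27me2·K36me1 (sharing one RT so they co-elute) and the
    near-isobaric K27me3 / K27ac pair that the m/z tolerance must resolve.
    """
    h3 = load_h3_sequence()
    k27 = next(p for p in ptm_model.digest(h3, protein_id="H3") if p.start == 27)
    abundances = {
        "K27un-K36un-K37un": 0.25,
        "K27me1-K36un-K37un": 0.12,
        "K27me2-K36un-K37un": 0.10,
        "K27me3-K36un-K37un": 0.20,
        "K27ac-K36un-K37un": 0.05,
        "K27me1-K36me2-K37un": 0.16,
        "K27me2-K36me1-K37un": 0.12,
    }
    rts = {
        "K27un-K36un-K37un": 30.0,
        "K27me1-K36un-K37un": 28.0,
        "K27me2-K36un-K37un": 26.0,
        "K27me3-K36un-K37un": 29.5,
        "K27ac-K36un-K37un": 33.0,
        "K27me1-K36me2-K37un": 27.0,  # co-elutes with its positional isomer
        "K27me2-K36me1-K37un": 27.0,
    }
    return PtmGroundTruth(k27, abundances, rts, seed=seed,
                          area_sigma=area_sigma, fragment_noise=fragment_noise)


load_h3_sequence = ptm_model.load_h3_sequence


# ---------------------------------------------------------------------------
# Arm 2: two-condition spike-in ChIP experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Domain:
    """A true enriched domain with its enrichment level above background."""

    chrom: str
    start: int
    end: int
    enrichment: float


@dataclass
class ChipRxGroundTruth:
    """Ground truth for a two-condition spike-in ChIP experiment.

    ``depth`` is a per-sample sequencing-depth multiplier on the expected
    per-bin read count; ``spikein_reads`` gives each sample's spike-in
    genome read count.  With ``poisson=False`` the emitted tracks equal the
    expected coverage exactly (the zero-noise setting).
    """

    genome: str
    chrom_lengths: dict[str, int]
    domains: dict[str, list[Domain]]  # condition -> true domains
    background: float
    depth: dict[str, float]  # sample id -> depth multiplier
    spikein_reads: dict[str, int]
    genes: list[GeneModel]
    seed: int
    bin_size: int = 20
    read_length: int = 50
    spikein_genome_size: int = 140_000_000
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.background < 0:
            raise SimulationError("background must be >= 0")
        if self.read_length <= 0:
            raise SimulationError("read length must be > 0")
        for cond, doms in self.domains.items():
            for d in doms:
                if d.chrom not in self.chrom_lengths:
                    raise SimulationError(f"{cond}: domain on unknown chromosome {d.chrom}")
                if d.start < 0 or d.end > self.chrom_lengths[d.chrom] or d.start >= d.end:
                    raise SimulationError(f"{cond}: domain out of chromosome bounds: {d}")
                if d.enrichment <= self.background:
                    raise SimulationError(
                        f"{cond}: enrichment {d.enrichment} must exceed background"
                    )
        if set(self.depth) != set(self.spikein_reads):
            raise SimulationError("depth and spike-in counts must cover the same samples")
        for sid, n in self.spikein_reads.items():
            if n <= 0:
                raise SimulationError(f"sample {sid}: spike-in read count must be > 0")

    def sample_condition(self, sample_id: str) -> str:
        return sample_id.rsplit("_rep", 1)[0]


def _expected_coverage(truth: ChipRxGroundTruth, condition: str, depth: float
                       ) -> dict[str, np.ndarray]:
    """Expected per-bin read count; partial bins weighted by covered bases."""
    b = truth.bin_size
    lam: dict[str, np.ndarray] = {}
    for chrom, length in truth.chrom_lengths.items():
        n_bins = -(-length // b)
        covered = np.minimum(b, length - np.arange(n_bins) * b)
        lam[chrom] = truth.background * depth * (covered / b)
    for d in truth.domains.get(condition, []):
        arr = lam[d.chrom]
        first, last = d.start // b, (d.end - 1) // b
        for k in range(first, last + 1):
            lo, hi = max(d.start, k * b), min(d.end, (k + 1) * b)
            arr[k] += d.enrichment * depth * (hi - lo) / b
    return lam


def simulate_chiprx_experiment(
    truth: ChipRxGroundTruth,
) -> tuple[list[ChipSample], dict[str, PeakSet], list[GeneModel]]:
    """Emit per-sample raw binned coverage, spike-in counts and called peaks.

    Counts are Poisson around depth x (background + enrichment); called peak
    intervals equal the true domains so downstream interval logic is tested
    against known truth.  Deterministic for a fixed seed.
    """
    samples: list[ChipSample] = []
    for i, sid in enumerate(sorted(truth.depth)):
        rng = np.random.default_rng((truth.seed, i))
        condition = truth.sample_condition(sid)
        lam = _expected_coverage(truth, condition, truth.depth[sid])
        values = {}
        for chrom in sorted(lam):
            values[chrom] = (
                rng.poisson(lam[chrom]).astype(float) if truth.poisson else lam[chrom]
            )
        track = GenomicTrack(truth.genome, truth.bin_size, dict(truth.chrom_lengths), values)
        replicate = int(sid.rsplit("_rep", 1)[1]) if "_rep" in sid else 0
        samples.append(
            ChipSample(
                sid,
                condition,
                replicate,
                primary_count=int(round(sum(v.sum() for v in values.values()))),
                spikein_count=truth.spikein_reads[sid],
                track=track,
            )
        )
    peak_sets = {
        cond: PeakSet(
            cond,
            [Peak(d.chrom, d.start, d.end, name=f"{cond}_{i}", score=d.enrichment)
             for i, d in enumerate(doms)],
            provenance="true domains",
        )
        for cond, doms in truth.domains.items()
    }
    return samples, peak_sets, list(truth.genes)


def demo_chiprx_truth(
    seed: int,
    n_base_domains: int = 20,
    k_new_domains: int = 8,
    background: float = 0.2,
    enrichment: float = 2.0,
    depth_b_multiplier: float = 1.5,
    spikein_fraction: float = 0.05,
    poisson: bool = True,
    conditions: tuple[str, str] = ("A", "B"),
) -> ChipRxGroundTruth:
    """Two-condition study design: condition B = A's domains plus k new ones.

    Genes are tiled regularly (4 kb bodies, 12 kb spacing, alternating
    strands) on one chromosome; each domain covers one gene body, so
    domain-gain recovery can be scored gene by gene.  Condition B is
    sequenced ``depth_b_multiplier`` times deeper, with spike-in counts
    proportional to depth — exactly the imbalance Rx normalization must
    undo.  Two replicates per condition.
    """
    gene_body, spacing, offset = 4_000, 12_000, 4_000
    n_genes = 2 * (n_base_domains + k_new_domains)
    chrom_len = offset + n_genes * spacing + offset
    chrom = "chr1"
    genes = []
    for i in range(n_genes):
        start = offset + i * spacing
        strand = "+" if i % 2 == 0 else "-"
        tss, tes = (start, start + gene_body) if strand == "+" else (start + gene_body, start)
        genes.append(GeneModel(f"gene{i:03d}", chrom, strand, tss, tes))

    # Even-indexed genes host basal domains; a block of odd-indexed genes
    # hosts the domains gained in condition B.
    base = [
        Domain(chrom, g.start, g.end, enrichment)
        for g in genes[: 2 * n_base_domains : 2]
    ]
    new = [
        Domain(chrom, g.start, g.end, enrichment)
        for g in genes[2 * n_base_domains :: 2][:k_new_domains]
    ]
    cond_a, cond_b = conditions
    domains = {cond_a: base, cond_b: base + new}

    base_reads = 4_000_000
    depth, spikein = {}, {}
    for cond, mult in ((cond_a, 1.0), (cond_b, depth_b_multiplier)):
        for rep in (1, 2):
            sid = f"{cond}_rep{rep}"
            depth[sid] = mult
            spikein[sid] = int(round(base_reads * spikein_fraction * mult))
    return ChipRxGroundTruth(
        genome="synthetic",
        chrom_lengths={chrom: chrom_len},
        domains=domains,
        background=background,
        depth=depth,
        spikein_reads=spikein,
        genes=genes,
        seed=seed,
        poisson=poisson,
    )


def new_domain_gene_ids(truth: ChipRxGroundTruth, cond_a: str, cond_b: str) -> set[str]:
    """Gene ids whose bodies coincide with domains present only in B."""
    base = {(d.chrom, d.start, d.end) for d in truth.domains[cond_a]}
    gained = [d for d in truth.domains[cond_b] if (d.chrom, d.start, d.end) not in base]
    ids = set()
    for d in gained:
        for g in truth.genes:
            if g.chrom == d.chrom and g.start < d.end and d.start < g.end:
                ids.add(g.gene_id)
    return ids
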