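"""Text-format adapters: BED6, bedGraph, gene TSV / GTF-lite, peak and
spectrum TSVs, YAML schemes.

All canonical formats are plain text so round trips are bit-exact at the
stated precision (tracks are written with 6 decimals).  Coordinates are
0-based half-open internally; GTF's 1-based inclusive convention is
converted at parse time.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from epiquant.chiprx import ChipRxError, GenomicTrack
from epiquant.domains import GeneModel, Peak, PeakSet
from epiquant.ptm_model import DerivatizationScheme
from epiquant.ptm_quant import Ms2Spectrum, XicPeak


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path, self.line_no = str(path), line_no


# -- BED6 peaks -------------------------------------------------------------


def write_bed(peak_set: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peak_set.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t{p.strand}\n")


def read_bed(path, label: str | None = None) -> PeakSet:
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, i, "BED line needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(path, i, "non-integer coordinates") from None
            if start >= end:
                raise ParseError(path, i, f"start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            peaks.append(Peak(parts[0], start, end, name, score, strand))
    return PeakSet(label or Path(path).stem, peaks)


# -- bedGraph tracks --------------------------------------------------------


def write_bedgraph(track: GenomicTrack, path) -> None:
    """Write one line per bin with 6-decimal values (zeros included)."""
    b = track.bin_size
    with open(path, "w") as fh:
        fh.write(f"# genome={track.genome} bin_size={b} normalized={int(track.normalized)}\n")
        for chrom in sorted(track.values):
            length = track.chrom_lengths[chrom]
            for k, v in enumerate(track.values[chrom]):
                fh.write(f"{chrom}\t{k * b}\t{min((k + 1) * b, length)}\t{v:.6f}\n")


def read_bedgraph(path, genome: str = "genome", bin_size: int | None = None,
                  chrom_lengths: dict[str, int] | None = None) -> GenomicTrack:
    """Read a fixed-step bedGraph back into a binned track.

    Lines may arrive unsorted (accepted with a warning and sorted
    internally).  Bin size and chromosome lengths are inferred from the
    intervals unless given; a header line written by :func:`write_bedgraph`
    restores the genome id and normalization flag.
    """
    rows: list[tuple[str, int, int, float]] = []
    normalized = False
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    key, _, val = tok.partition("=")
                    if key == "genome":
                        genome = val
                    elif key == "bin_size":
                        bin_size = int(val)
                    elif key == "normalized":
                        normalized = bool(int(val))
                continue
            if line.startswith(("track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(path, i, "bedGraph line needs 4 columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError:
                raise ParseError(path, i, "malformed bedGraph record") from None
    if not rows:
        raise ParseError(path, 0, "empty bedGraph")
    if rows != sorted(rows, key=lambda r: (r[0], r[1])):
        warnings.warn(f"{path}: unsorted bedGraph accepted, sorting internally",
                      stacklevel=2)
        rows.sort(key=lambda r: (r[0], r[1]))
    if bin_size is None:
        bin_size = max(e - s for _, s, e, _ in rows)
    if chrom_lengths is None:
        chrom_lengths = {}
        for chrom, _, end, _ in rows:
            chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), end)
    values = {
        c: np.zeros(-(-length // bin_size)) for c, length in chrom_lengths.items()
    }
    for chrom, start, end, val in rows:
        if chrom not in values:
            raise ChipRxError(f"unknown chromosome {chrom!r}")
        values[chrom][start // bin_size] = val
    return GenomicTrack(genome, bin_size, chrom_lengths, values, normalized)


# -- gene models ------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tes", "biotype"]


def write_genes(genes: Sequence[GeneModel], path) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
             "tss": g.tss, "tes": g.tes, "biotype": g.biotype}
            for g in genes
        ],
        columns=GENE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_genes(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"gene TSV missing columns {sorted(missing)}")
    return [
        GeneModel(
            str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss), int(r.tes),
            str(getattr(r, "biotype", "protein_coding")),
        )
        for r in df.itertuples()
    ]


def read_gtf_genes(path) -> list[GeneModel]:
    """Minimal GTF reader: ``gene`` feature lines with a gene_id attribute.

    GTF is 1-based inclusive; coordinates convert to 0-based half-open, and
    the TSS is taken strand-aware (start for +, end for -).
    """
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(path, i, "GTF line needs 9 columns")
            if parts[2] != "gene":
                continue
            try:
                start0, end0 = int(parts[3]) - 1, int(parts[4])
            except ValueError:
                raise ParseError(path, i, "non-integer GTF coordinates") from None
            strand = parts[6]
            gene_id = None
            for attr in parts[8].split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip('" ')
            if gene_id is None:
                raise ParseError(path, i, "gene line without gene_id attribute")
            tss, tes = (start0, end0) if strand == "+" else (end0, start0)
            genes.append(GeneModel(gene_id, parts[0], strand, tss, tes))
    return genes


def write_gtf_genes(genes: Sequence[GeneModel], path, source: str = "epiquant") -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )


# -- MS peak / spectrum TSVs ------------------------------------------------

PEAK_COLUMNS = ["sample", "mz", "z", "rt", "area"]


def write_xic_peaks(peaks: Sequence[XicPeak], path) -> None:
    pd.DataFrame(
        [{"sample": p.sample, "mz": f"{p.mz:.6f}", "z": p.charge,
          "rt": f"{p.rt:.4f}", "area": f"{p.area:.6f}"} for p in peaks],
        columns=PEAK_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_xic_peaks(path) -> list[XicPeak]:
    df = pd.read_csv(path, sep="\t")
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"peak TSV missing columns {sorted(missing)}")
    return [
        XicPeak(str(r.sample), float(r.mz), int(r.z), float(r.rt), float(r.area))
        for r in df.itertuples()
    ]


def write_spectra(spectra: Sequence[Ms2Spectrum], path) -> None:
    """One row per spectrum; fragments as ``mz:intensity`` pairs joined by ';'."""
    with open(path, "w") as fh:
        fh.write("precursor_mz\tz\trt\tfragments\n")
        for s in spectra:
            frags = ";".join(f"{m:.6f}:{i:.6f}" for m, i in s.fragments)
            fh.write(f"{s.precursor_mz:.6f}\t{s.charge}\t{s.rt:.4f}\t{frags}\n")


def read_spectra(path) -> list[Ms2Spectrum]:
    spectra = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["precursor_mz", "z", "rt", "fragments"]:
            raise ParseError(path, 1, "unexpected spectrum TSV header")
        for i, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(path, i, "spectrum line needs 4 columns")
            try:
                frags = tuple(
                    (float(p.split(":")[0]), float(p.split(":")[1]))
                    for p in parts[3].split(";")
                )
                spectra.append(
                    Ms2Spectrum(float(parts[0]), int(parts[1]), float(parts[2]), frags)
                )
            except (ValueError, IndexError):
                raise ParseError(path, i, "malformed spectrum record") from None
    return spectra


# -- abundance / fold-change tables ----------------------------------------


def write_abundance(table, path) -> None:
    """Long-format TSV: peptide, kind (combination|marginal), label, percent."""
    rows = []
    for kind, mapping in (("combination", table.combinations),
                          ("marginal", table.marginals)):
        for pep, entries in sorted(mapping.items()):
            for lab, pct in sorted(entries.items()):
                rows.append({"peptide": pep, "kind": kind, "label": lab,
                             "percent": f"{pct:.6f}"})
    pd.DataFrame(rows, columns=["peptide", "kind", "label", "percent"]).to_csv(
        path, sep="\t", index=False
    )


def read_abundance(path):
    from epiquant.ptm_quant import AbundanceTable

    df = pd.read_csv(path, sep="\t")
    table = AbundanceTable()
    for r in df.itertuples():
        target = table.combinations if r.kind == "combination" else table.marginals
        target.setdefault(r.peptide, {})[r.label] = float(r.percent)
    return table


def write_fold_change(fc, path) -> None:
    rows = []
    for kind, mapping in (("combination", fc.combinations), ("marginal", fc.marginals)):
        for pep, entries in sorted(mapping.items()):
            for lab, val in sorted(entries.items()):
                rows.append({"peptide": pep, "kind": kind, "label": lab,
                             "log1p5_fold_change": f"{val:.6f}"})
    pd.DataFrame(
        rows, columns=["peptide", "kind", "label", "log1p5_fold_change"]
    ).to_csv(path, sep="\t", index=False)


# -- YAML scheme / config ---------------------------------------------------


def write_scheme(scheme: DerivatizationScheme, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "heavy_methyl_delta": scheme.heavy_methyl_delta,
                "light_methyl_delta": scheme.light_methyl_delta,
                "acetyl_delta": scheme.acetyl_delta,
                "propionyl_delta": scheme.propionyl_delta,
                "heavy_installed": dict(scheme.heavy_installed),
            },
            fh,
        )


def read_scheme(path) -> DerivatizationScheme:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return DerivatizationScheme(**data)


def write_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
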