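"""Core data model and readers/writers for the formats the pipeline touches.

Coordinates are 0-based half-open throughout; VCF's 1-based positions are
converted on read.  Genotypes are diploid dosages of the alternate allele
(0, 1, 2) with -1 for missing; half-called genotypes are treated as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopulationMap",
    "GenomicWindow",
    "WindowAlignment",
    "AlleleFrequencyTable",
    "read_vcf",
    "write_vcf",
    "allele_frequencies",
    "iterate_windows",
    "read_fasta_window",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_table",
    "write_table",
    "read_popmap",
    "write_popmap",
]


class EmptyDataError(ValueError):
    """No usable records remained after filtering."""


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNV dosages per sample with site coordinates.

    Attributes
    ----------
    chrom : array of str, one per site
    pos : array of int, 0-based positions, strictly increasing per chromosome
    ref, alt : arrays of single-character alleles
    dosage : int8 array, shape (n_sites, n_samples), values in {0,1,2,-1}
    samples : ordered sample identifiers
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != (n_sites={len(self.pos)}, n_samples={len(self.samples)})"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_mask(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Subset of sites selected by a boolean mask (no copy of samples)."""
        return GenotypeMatrix(
            self.chrom[mask], self.pos[mask], self.ref[mask], self.alt[mask], self.dosage[mask], self.samples
        )


@dataclass
class PopulationMap:
    """Mapping of sample id -> population label with an ordered label list."""

    assignments: dict[str, str]
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for p in self.assignments.values():
            if p not in seen:
                seen.append(p)
        if not self.populations:
            self.populations = seen
        else:
            missing = set(seen) - set(self.populations)
            if missing:
                raise ValueError(f"populations used but not listed: {sorted(missing)}")

    def samples_of(self, population: str) -> list[str]:
        out = [s for s, p in self.assignments.items() if p == population]
        if not out:
            raise KeyError(f"population {population!r} has no samples")
        return out

    def __getitem__(self, sample: str) -> str:
        return self.assignments[sample]

    def __contains__(self, sample: str) -> bool:
        return sample in self.assignments


@dataclass(frozen=True)
class GenomicWindow:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    partial: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class WindowAlignment:
    """Equal-length sequences for one genomic window.

    records: list of (sample id, population label, sequence over {A,C,G,T,N}).
    """

    window: GenomicWindow
    records: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        lengths = {len(seq) for _, _, seq in self.records}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment in {self.window}: lengths {sorted(lengths)}")
        if self.records and len(self.records[0][2]) > self.window.length:
            raise ValueError("alignment longer than its window")

    @property
    def n_seqs(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0][2]) if self.records else 0

    def matrix(self) -> np.ndarray:
        """Sequences as a uint8 byte matrix, shape (n_seqs, length)."""
        return np.frombuffer("".join(s for _, _, s in self.records).encode(), dtype=np.uint8).reshape(
            self.n_seqs, self.length
        )

    def samples(self) -> list[str]:
        return [s for s, _, _ in self.records]


@dataclass
class AlleleFrequencyTable:
    """Per-site derived-allele frequency per population.

    freq has shape (n_sites, n_populations); NaN marks a population with no
    called alleles at that site.  All f-statistics consume this table.
    """

    chrom: np.ndarray
    pos: np.ndarray
    freq: np.ndarray
    populations: list[str]
    n_chrom: np.ndarray | None = None  # called chromosome counts, same shape as freq

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.pos), len(self.populations)):
            raise ValueError("freq shape mismatch")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.freq, initial=0.0) < 0 or np.nanmax(self.freq, initial=0.0) > 1:
                raise ValueError("frequencies must lie in [0,1]")
        if self.n_chrom is not None:
            self.n_chrom = np.asarray(self.n_chrom, dtype=float)
            if self.n_chrom.shape != self.freq.shape:
                raise ValueError("n_chrom shape mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def column(self, population: str) -> np.ndarray:
        return self.freq[:, self.populations.index(population)]

    def counts_column(self, population: str) -> np.ndarray | None:
        if self.n_chrom is None:
            return None
        return self.n_chrom[:, self.populations.index(population)]

    def site_mask(self, mask: np.ndarray) -> "AlleleFrequencyTable":
        return AlleleFrequencyTable(
            self.chrom[mask],
            self.pos[mask],
            self.freq[mask],
            self.populations,
            None if self.n_chrom is None else self.n_chrom[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos})
        for j, p in enumerate(self.populations):
            df[p] = self.freq[:, j]
        return df


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, region: str | None = None) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF 4.x file into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNV records are skipped (counts logged).  Phasing is
    ignored; half-called genotypes become missing.  ``region`` is a
    ``chrom:start-end`` string forwarded to cyvcf2 (requires an index) or a
    bare chromosome name.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare exceptions on unreadable files
        raise OSError(f"cannot read VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    last: tuple[str, int] | None = None

    iterator = vcf(region) if region else vcf
    for var in iterator:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1 or var.ALT[0] not in "ACGT":
            skipped += 1
            continue
        key = (var.CHROM, var.POS)
        if last is not None and key[0] == last[0] and key[1] <= last[1]:
            skipped += 1  # duplicate/unsorted position (e.g. split multiallelic)
            continue
        last = key
        gt = np.asarray(var.genotypes, dtype=np.int16)  # (n_samples, 2 or 3) last col = phased flag
        alleles = gt[:, :2]
        dos = alleles.sum(axis=1).astype(np.int8)
        dos[(alleles < 0).any(axis=1)] = MISSING
        chroms.append(var.CHROM)
        positions.append(var.POS - 1)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(dos)
    vcf.close()

    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNV/duplicate records", skipped)
    if not rows:
        raise EmptyDataError(f"no biallelic SNVs in {path}")
    logger.info("read_vcf: retained %d sites x %d samples", len(rows), len(samples))
    return GenotypeMatrix(
        np.array(chroms, dtype=object),
        np.array(positions),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        np.vstack(rows),
        samples,
    )


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Emit a minimal VCF 4.2 file (GT only) for a genotype matrix."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(geno.chrom):
            length = int(geno.pos[geno.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.samples) + "\n")
        for i in range(geno.n_sites):
            gts = "\t".join(code[int(d)] for d in geno.dosage[i])
            fh.write(
                f"{geno.chrom[i]}\t{geno.pos[i] + 1}\t.\t{geno.ref[i]}\t{geno.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Allele frequencies


def allele_frequencies(
    geno: GenotypeMatrix,
    pops: PopulationMap,
    polarize_by: str | None = None,
) -> AlleleFrequencyTable:
    """Per-population allele frequencies, optionally polarized by an outgroup.

    Frequency = (sum of dosages) / (2 x non-missing samples).  When
    ``polarize_by`` is given, sites where that population is polymorphic or
    entirely missing are dropped, and frequencies are reported for the allele
    absent from the polarizing population (the derived allele).
    """
    unassigned = [s for s in geno.samples if s not in pops]
    if unassigned:
        raise KeyError(f"samples without population label: {unassigned}")
    pop_list = [p for p in pops.populations if any(pops[s] == p for s in geno.samples)]
    sample_idx = {p: [i for i, s in enumerate(geno.samples) if pops[s] == p] for p in pop_list}

    n_sites = geno.n_sites
    freq = np.full((n_sites, len(pop_list)), np.nan)
    counts = np.zeros((n_sites, len(pop_list)))
    for j, p in enumerate(pop_list):
        d = geno.dosage[:, sample_idx[p]].astype(float)
        called = d >= 0
        n_alleles = 2.0 * called.sum(axis=1)
        alt_sum = np.where(called, d, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[:, j] = np.where(n_alleles > 0, alt_sum / n_alleles, np.nan)
        counts[:, j] = n_alleles

    keep = np.ones(n_sites, dtype=bool)
    if polarize_by is not None:
        if polarize_by not in pop_list:
            raise KeyError(f"polarizing population {polarize_by!r} not present")
        k = pop_list.index(polarize_by)
        og = freq[:, k]
        fixed_ref = og == 0.0
        fixed_alt = og == 1.0
        keep = fixed_ref | fixed_alt
        freq = np.where(fixed_alt[:, None], 1.0 - freq, freq)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("allele_frequencies: dropped %d sites (outgroup polymorphic or missing)", dropped)

    table = AlleleFrequencyTable(geno.chrom[keep], geno.pos[keep], freq[keep], pop_list, counts[keep])
    if table.n_sites == 0:
        raise EmptyDataError("no sites retained after polarization")
    return table


def alignment_frequencies(
    alignment: "WindowAlignment", polarize_by: str
) -> AlleleFrequencyTable:
    """Derived-allele frequencies per population from a window alignment.

    Retains biallelic sites at which the polarizing (outgroup) population
    is present and fixed; the derived allele is the one absent from the
    outgroup.  Site coordinates are window-relative offsets added to the
    window start.  Raises :class:`EmptyDataError` if nothing is retained.
    """
    pops_present: list[str] = []
    for _, p, _ in alignment.records:
        if p not in pops_present:
            pops_present.append(p)
    if polarize_by not in pops_present:
        raise KeyError(f"polarizing population {polarize_by!r} absent from alignment")
    mat = alignment.matrix()
    n_code = ord("N")
    pop_rows = {p: [i for i, (_, q, _) in enumerate(alignment.records) if q == p] for p in pops_present}

    og = mat[pop_rows[polarize_by]]
    offs: list[int] = []
    freq_rows: list[list[float]] = []
    count_rows: list[list[float]] = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        called = col[col != n_code]
        alleles = np.unique(called)
        if len(alleles) != 2:
            continue
        og_col = og[:, j]
        og_called = og_col[og_col != n_code]
        og_alleles = np.unique(og_called)
        if len(og_alleles) != 1:
            continue  # outgroup missing or polymorphic
        derived = alleles[alleles != og_alleles[0]]
        if len(derived) != 1:
            continue  # both alleles present in outgroup consensus
        row, crow = [], []
        for p in pops_present:
            sub = col[pop_rows[p]]
            sub = sub[sub != n_code]
            crow.append(float(len(sub)))
            row.append(float((sub == derived[0]).sum()) / len(sub) if len(sub) else np.nan)
        offs.append(j)
        freq_rows.append(row)
        count_rows.append(crow)
    if not offs:
        raise EmptyDataError(f"no polarizable biallelic sites in {alignment.window}")
    w = alignment.window
    return AlleleFrequencyTable(
        np.full(len(offs), w.chrom, dtype=object),
        w.start + np.array(offs, dtype=np.int64),
        np.array(freq_rows),
        pops_present,
        np.array(count_rows),
    )


# ---------------------------------------------------------------------------
# Windows


def iterate_windows(
    chrom_lengths: Mapping[str, int],
    window_length: int = 200_000,
    step: int | None = None,
) -> Iterator[GenomicWindow]:
    """Tile each chromosome with windows from coordinate 0.

    The default step equals the window length (non-overlapping tiling); a
    trailing partial window is emitted with ``partial=True``.
    """
    if window_length <= 0:
        raise ValueError("window length must be positive")
    if step is None:
        step = window_length
    if step <= 0:
        raise ValueError("step must be positive")
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            end = min(start + window_length, length)
            yield GenomicWindow(chrom, start, end, partial=end - start < window_length)
            start += step


def windows_of_table(
    table: AlleleFrequencyTable, window_length: int = 200_000, step: int | None = None
) -> Iterator[tuple[GenomicWindow, np.ndarray]]:
    """Pair each tiling window with a boolean site mask into ``table``.

    Chromosome extents are taken as ``max(pos)+1`` per chromosome present.
    """
    lengths = {str(c): int(table.pos[table.chrom == c].max()) + 1 for c in pd.unique(table.chrom)}
    for win in iterate_windows(lengths, window_length, step):
        mask = (table.chrom == win.chrom) & (table.pos >= win.start) & (table.pos < win.end)
        yield win, mask


# ---------------------------------------------------------------------------
# FASTA / Newick / tables / popmap

_HEADER_SEP = "|"


def write_fasta(alignment: WindowAlignment, path: str | Path) -> None:
    """Write a window alignment; headers are ``>sample|population`` and the
    window is recorded on a leading comment-style ``;`` line understood by
    :func:`read_fasta_window`."""
    with open(path, "w") as fh:
        w = alignment.window
        fh.write(f";window {w.chrom} {w.start} {w.end} {int(w.partial)}\n")
        for sample, pop, seq in alignment.records:
            fh.write(f">{sample}{_HEADER_SEP}{pop}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta_window(path: str | Path, window: GenomicWindow | None = None) -> WindowAlignment:
    """Read one window alignment from FASTA.

    If the file lacks the ``;window`` preamble and no window is supplied, a
    window spanning the alignment length on chromosome ``"unknown"`` is used.
    """
    records: list[tuple[str, str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(";window"):
                _, chrom, s, e, p = line.split()
                window = GenomicWindow(chrom, int(s), int(e), bool(int(p)))
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(_split_header(name, "".join(chunks)))
                name, chunks = line[1:], []
            elif line and not line.startswith(";"):
                if name is None:
                    raise FormatError(f"{path}: sequence data before first header")
                chunks.append(line.strip().upper())
    if name is not None:
        records.append(_split_header(name, "".join(chunks)))
    if not records:
        raise EmptyDataError(f"no sequences in {path}")
    if window is None:
        window = GenomicWindow("unknown", 0, len(records[0][2]))
    return WindowAlignment(window, records)


def _split_header(header: str, seq: str) -> tuple[str, str, str]:
    if _HEADER_SEP in header:
        sample, pop = header.split(_HEADER_SEP, 1)
    else:
        sample, pop = header.split()[0], ""
    bad = set(seq) - set("ACGTN-")
    if bad:
        raise FormatError(f"sequence {sample}: unexpected characters {sorted(bad)}")
    return sample, pop, seq


def read_newick(path_or_string: str | Path):
    """Parse a Newick tree (branch lengths + integer support) into dendropy."""
    import dendropy

    text = str(path_or_string)
    if "(" not in text:
        text = Path(path_or_string).read_text()
    try:
        # internal labels (bootstrap supports) stay node labels, not taxa
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True, preserve_underscores=True
        )
    except Exception as exc:
        raise FormatError(f"unparseable Newick: {exc}") from exc
    return tree


def write_newick(tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated stat table with a header line; NA encodes missing."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_popmap(pops: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in pops.assignments.items():
            fh.write(f"{sample}\t{pop}\n")


def read_popmap(path: str | Path) -> PopulationMap:
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"popmap line needs 'sample<TAB>population': {line!r}")
            assignments[parts[0]] = parts[1]
    return PopulationMap(assignments)
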