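"""Reading and writing genotype tables.

The canonical dialect is a plain CSV that mirrors the classic three-header-row
worksheet layout used by spreadsheet population-genetics tools:

* row 1: ``n_loci, n_samples, n_pops, size_pop1, size_pop2, ...``
* row 2: ``title, , , name_pop1, name_pop2, ...`` (population names aligned
  over their size cells)
* optional region row: ``Region, , , region_pop1, region_pop2, ...``
* row 3: ``Sample, Pop, locus1, [blank], locus2, [blank], ...`` — diploid data
  take two columns per locus with the second header cell blank; haploid and
  binary data take one.  If the row ends with ``..., , X, Y`` a coordinate
  block follows the genotypes in every data row.
* data rows: ``sample_id, pop, alleles..., [blank, x, y]``

Allele codes are integers, 0 = missing.  Exports cover GenePop, STRUCTURE
(two-row layout) and FSTAT; alleles are zero-padded to three digits, so codes
above 999 are rejected.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np

from .core import (
    MISSING_BINARY,
    AlleleFreqTable,
    DataType,
    GenotypeDataset,
    LocusInfo,
    ValidationError,
    validate_dataset,
)

__all__ = [
    "read_canonical",
    "write_canonical",
    "read_allele_freq_table",
    "write_allele_freq_table",
    "export_genepop",
    "export_structure",
    "export_fstat",
]


def _cell_int(cell: str, where: str) -> int:
    try:
        return int(cell.strip())
    except ValueError:
        raise ValidationError(f"non-integer cell {cell!r} in {where}") from None


def read_canonical(path: str | Path | _io.StringIO, data_type: str | DataType) -> GenotypeDataset:
    """Parse the canonical CSV dialect into a validated dataset."""
    data_type = DataType(data_type)
    if isinstance(path, _io.StringIO):
        rows = list(csv.reader(path))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if len(rows) < 4:
        raise ValidationError("canonical file needs 3 header rows plus data")

    hdr = rows[0]
    n_loci = _cell_int(hdr[0], "header row 1 (n_loci)")
    n_samples = _cell_int(hdr[1], "header row 1 (n_samples)")
    n_pops = _cell_int(hdr[2], "header row 1 (n_pops)")
    pop_sizes = [_cell_int(c, "pop sizes") for c in hdr[3 : 3 + n_pops]]
    if len(pop_sizes) != n_pops:
        raise ValidationError("population count mismatch: fewer size cells than n_pops")
    if sum(pop_sizes) != n_samples:
        raise ValidationError(
            f"population count mismatch: pop sizes sum to {sum(pop_sizes)}, "
            f"header declares {n_samples} samples"
        )

    title_row = rows[1]
    title = title_row[0].strip() if title_row else ""
    pop_names = [c.strip() for c in title_row[3 : 3 + n_pops]]
    if len(pop_names) != n_pops or any(not p for p in pop_names):
        raise ValidationError("population count mismatch: missing population names in row 2")

    next_i = 2
    regions: dict[str, str] | None = None
    if rows[next_i] and rows[next_i][0].strip().lower() == "region":
        rnames = [c.strip() for c in rows[next_i][3 : 3 + n_pops]]
        if len(rnames) != n_pops or any(not r for r in rnames):
            raise ValidationError("region row must name a region for every population")
        regions = dict(zip(pop_names, rnames))
        next_i += 1

    locus_row = rows[next_i]
    next_i += 1
    if len(locus_row) < 2 or locus_row[0].strip().lower() != "sample":
        raise ValidationError('row 3 must start with "Sample","Pop"')
    ploidy = data_type.ploidy
    cells = [c.strip() for c in locus_row[2:]]
    has_coords = len(cells) >= 2 and cells[-2:] == ["X", "Y"]
    geno_cells = cells[:-3] if has_coords else cells  # drop blank spacer + X,Y
    if has_coords and (len(cells) < 3 or cells[-3] != ""):
        geno_cells = cells[:-2]
    locus_names = [geno_cells[i] for i in range(0, len(geno_cells), ploidy)]
    locus_names = [n for n in locus_names if n]
    if len(locus_names) != n_loci:
        raise ValidationError(
            f"locus count mismatch: header declares {n_loci}, row 3 names {len(locus_names)}"
        )

    n_geno_cols = ploidy * n_loci
    sample_ids: list[str] = []
    pops: list[str] = []
    alleles = np.zeros((n_samples, n_geno_cols), dtype=np.int64)
    coords = np.zeros((n_samples, 2)) if has_coords else None
    data_rows = rows[next_i:]
    if len(data_rows) != n_samples:
        raise ValidationError(
            f"sample count mismatch: header declares {n_samples}, file has {len(data_rows)} data rows"
        )
    for i, row in enumerate(data_rows):
        if len(row) < 2 + n_geno_cols:
            raise ValidationError(f"data row {i + 1} too short ({row[:2]})")
        sample_ids.append(row[0].strip())
        pops.append(row[1].strip())
        for j in range(n_geno_cols):
            alleles[i, j] = _cell_int(row[2 + j], f"data row {i + 1}")
        if has_coords:
            tail = [c for c in row[2 + n_geno_cols :] if c.strip()]
            if len(tail) < 2:
                raise ValidationError(
                    f"coordinate columns declared but absent for sample {row[0]!r}"
                )
            coords[i] = [float(tail[0]), float(tail[1])]

    seen = list(dict.fromkeys(pops))
    if seen != pop_names:
        if set(seen) != set(pop_names):
            raise ValidationError(
                f"population count mismatch: header names {pop_names}, data contains {seen}"
            )
    for p, size in zip(pop_names, pop_sizes):
        actual = pops.count(p)
        if actual != size:
            raise ValidationError(
                f"population count mismatch: {p!r} declared {size}, found {actual}"
            )

    if data_type is DataType.BINARY:
        # bands are 1/0; since 0 already means "band absent", missing binary
        # cells are written as -1 in files (same code as in memory)
        if not np.isin(alleles, (MISSING_BINARY, 0, 1)).all():
            bad = sorted(set(alleles.ravel().tolist()) - {MISSING_BINARY, 0, 1})
            raise ValidationError(f"binary entry outside {{0,1,missing}}: {bad}")
    ds = GenotypeDataset(
        sample_ids=sample_ids,
        data_type=data_type,
        loci=[LocusInfo(n) for n in locus_names],
        alleles=alleles,
        pops=pops,
        regions=regions,
        coords=coords,
        title=title or "popstruct dataset",
    )
    return validate_dataset(ds)


def write_canonical(ds: GenotypeDataset, path: str | Path | None = None) -> str:
    """Serialize a dataset to the canonical CSV dialect (round-trip exact)."""
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    pop_names = ds.pop_names
    sizes = [len(ds.pop_indices(p)) for p in pop_names]
    w.writerow([ds.n_loci, ds.n_samples, len(pop_names), *sizes])
    w.writerow([ds.title, "", "", *pop_names])
    if ds.regions is not None:
        w.writerow(["Region", "", "", *[ds.regions[p] for p in pop_names]])
    locus_cells: list[str] = []
    for name in ds.locus_names:
        locus_cells.append(name)
        locus_cells.extend([""] * (ds.ploidy - 1))
    header = ["Sample", "Pop", *locus_cells]
    if ds.coords is not None:
        header += ["", "X", "Y"]
    w.writerow(header)
    for i, sid in enumerate(ds.sample_ids):
        row: list = [sid, ds.pops[i], *[int(a) for a in ds.alleles[i]]]
        if ds.coords is not None:
            row += ["", repr(float(ds.coords[i, 0])), repr(float(ds.coords[i, 1]))]
        w.writerow(row)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# published allele-frequency tables


def read_allele_freq_table(path: str | Path | _io.StringIO) -> AlleleFreqTable:
    """Read a published allele-frequency CSV.

    Layout: a header row ``Locus, Allele, pop1, pop2, ...``; then one block
    per locus with a row per allele (``locus, allele_code, freq...``) closed
    by an ``N`` row (``locus, N, gene_copies...``).  Per-(locus, pop)
    frequencies must sum to 1 within 0.01; small departures are renormalized,
    larger ones are an error.  The resulting table carries no genotypes, so
    downstream estimators run without sample-size corrections.
    """
    if isinstance(path, _io.StringIO):
        rows = list(csv.reader(path))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
    rows = [r for r in rows if any(c.strip() for c in r)]
    header = [c.strip() for c in rows[0]]
    if len(header) < 3 or header[0].lower() != "locus":
        raise ValidationError('allele-frequency file must start "Locus,Allele,<pops...>"')
    pops = header[2:]
    raw: dict[str, dict[int, list[float]]] = {}
    ns: dict[str, list[int]] = {}
    loci: list[str] = []
    for row in rows[1:]:
        locus = row[0].strip()
        if locus not in raw:
            raw[locus] = {}
            loci.append(locus)
        tag = row[1].strip()
        vals = row[2 : 2 + len(pops)]
        if tag.upper() == "N":
            ns[locus] = [int(float(v)) for v in vals]
        else:
            raw[locus][int(tag)] = [float(v) if v.strip() else 0.0 for v in vals]
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    n_typed: dict[tuple[str, str], int] = {}
    for locus in loci:
        if locus not in ns:
            raise ValidationError(f"missing N row for locus {locus!r}")
        for j, pop in enumerate(pops):
            col = {a: v[j] for a, v in raw[locus].items() if v[j] > 0}
            if not col:
                continue
            s = sum(col.values())
            if not (0.99 <= s <= 1.01):
                raise ValidationError(
                    f"frequencies for locus {locus!r}, population {pop!r} sum to {s:.4f}"
                )
            freqs[(locus, pop)] = {a: v / s for a, v in col.items()}
            n_typed[(locus, pop)] = ns[locus][j]
    return AlleleFreqTable(
        loci=loci, pops=pops, freqs=freqs, n_typed=n_typed, from_genotypes=False
    )


def write_allele_freq_table(table: AlleleFreqTable, path: str | Path | None = None) -> str:
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["Locus", "Allele", *table.pops])
    for locus in table.loci:
        for a in table.alleles_at(locus):
            w.writerow(
                [locus, a]
                + [table.freqs.get((locus, p), {}).get(a, 0.0) for p in table.pops]
            )
        w.writerow(
            [locus, "N"] + [table.n_typed.get((locus, p), 0) for p in table.pops]
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# exports


def _check_exportable(ds: GenotypeDataset) -> None:
    if ds.data_type is DataType.BINARY:
        raise ValidationError("binary data cannot be exported to allele-code formats")
    if ds.alleles.max(initial=0) > 999:
        bad = int(ds.alleles.max())
        raise ValidationError(f"allele exceeds 3-digit width: {bad}")


def export_genepop(ds: GenotypeDataset, path: str | Path | None = None) -> str:
    """GenePop dialect: title, one locus per line, Pop blocks, 3-digit alleles."""
    _check_exportable(ds)
    lines = [ds.title]
    lines.extend(ds.locus_names)
    for pop in ds.pop_names:
        lines.append("Pop")
        for i in ds.pop_indices(pop):
            genos = []
            for l in range(ds.n_loci):
                g = ds.locus_columns(l)[i]
                if ds.ploidy == 2:
                    genos.append(f"{g[0]:03d}{g[1]:03d}")
                else:
                    genos.append(f"{g[0]:03d}")
            lines.append(f"{ds.sample_ids[i]} ,  " + " ".join(genos))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def export_structure(ds: GenotypeDataset, path: str | Path | None = None) -> str:
    """STRUCTURE two-row layout: id, 1-based pop index, one allele per locus.

    Diploid individuals occupy two rows (one haploid genome per row);
    haploid individuals one.  Missing alleles are written as -9.
    """
    _check_exportable(ds)
    pop_index = {p: j + 1 for j, p in enumerate(ds.pop_names)}
    lines = ["\t".join(["", ""] + ds.locus_names)]
    for i, sid in enumerate(ds.sample_ids):
        for copy in range(ds.ploidy):
            vals = []
            for l in range(ds.n_loci):
                a = int(ds.locus_columns(l)[i][copy])
                vals.append("-9" if a == 0 else str(a))
            lines.append("\t".join([sid, str(pop_index[ds.pops[i]])] + vals))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def export_fstat(ds: GenotypeDataset, path: str | Path | None = None) -> str:
    """FSTAT .dat: 'np nl max_allele 3' header, locus names, pop-index rows."""
    _check_exportable(ds)
    pop_index = {p: j + 1 for j, p in enumerate(ds.pop_names)}
    max_allele = int(ds.alleles.max(initial=1))
    lines = [f"{len(ds.pop_names)} {ds.n_loci} {max_allele} 3"]
    lines.extend(ds.locus_names)
    for i in range(ds.n_samples):
        genos = []
        for l in range(ds.n_loci):
            g = ds.locus_columns(l)[i]
            genos.append("".join(f"{int(a):03d}" for a in g))
        lines.append(f"{pop_index[ds.pops[i]]} " + " ".join(genos))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
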