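"""Readers and writers for the plain-text interchange formats.

Supported formats:

* GENEPOP genotype files, 3-digits-per-allele dialect ("000000" = missing);
* STRUCTURE genotype files, two-rows-per-individual dialect (-9 = missing);
* ESRI ASCII grids with a NODATA_value header;
* labelled square CSV for dissimilarity matrices.

All round-trips are exact: integer allele sizes and raster cell values are
written without loss.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DistMatrix, GenotypeTable, MISSING_ALLELE, RasterGrid

_ALLELE_DIGITS = 3


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------

def write_genepop(gt: GenotypeTable, path, title: str = "genoscape export") -> None:
    lines = [title]
    lines.extend(gt.loci)
    current_pop = None
    for i in range(gt.n_ind):
        pop = gt.populations[i]
        if pop != current_pop:
            lines.append("POP")
            current_pop = pop
        genos = "".join(
            f"{gt.alleles[i, j, 0]:0{_ALLELE_DIGITS}d}{gt.alleles[i, j, 1]:0{_ALLELE_DIGITS}d} "
            for j in range(gt.n_loci)
        ).rstrip()
        lines.append(f"{gt.individuals[i]} ,  {genos}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genepop(path) -> GenotypeTable:
    """Read a GENEPOP file; population labels come from each POP block's first
    individual id (the GENEPOP convention), stripped of a trailing index."""
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    if not raw:
        raise ValueError("empty GENEPOP file")
    lines = raw[1:]  # title
    loci: list[str] = []
    i = 0
    while i < len(lines) and lines[i].strip().upper() != "POP":
        token = lines[i].strip()
        if token:
            # loci may be one-per-line or comma-separated on one line
            loci.extend(t.strip() for t in token.split(",") if t.strip())
        i += 1
    if i == len(lines):
        raise ValueError("no POP line found")
    individuals: list[str] = []
    pops: list[str] = []
    rows: list[list[int]] = []
    pop_counter = 0
    pop_label = ""
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.upper() == "POP":
            pop_counter += 1
            pop_label = ""
            continue
        name, _, genos = line.partition(",")
        name = name.strip()
        if not pop_label:
            # population label: individual-id prefix before a trailing "_k",
            # else the whole first id
            pop_label = name.rsplit("_", 1)[0] if "_" in name else name
        fields = genos.split()
        if len(fields) != len(loci):
            raise ValueError(f"individual {name!r} has {len(fields)} genotypes, "
                             f"expected {len(loci)}")
        row: list[int] = []
        for f in fields:
            if len(f) != 2 * _ALLELE_DIGITS or not f.isdigit():
                raise ValueError(f"malformed genotype {f!r} for {name!r}")
            row.extend((int(f[:_ALLELE_DIGITS]), int(f[_ALLELE_DIGITS:])))
        individuals.append(name)
        pops.append(pop_label)
        rows.append(row)
    alleles = np.array(rows, dtype=np.int64).reshape(len(rows), len(loci), 2)
    return GenotypeTable(alleles, individuals, np.array(pops, dtype=object), loci)


# ---------------------------------------------------------------------------
# STRUCTURE (two rows per individual)
# ---------------------------------------------------------------------------

_STRUCTURE_MISSING = -9


def write_structure(gt: GenotypeTable, path) -> None:
    pops = gt.pops
    pop_code = {p: k + 1 for k, p in enumerate(pops)}
    with open(path, "w") as fh:
        fh.write("\t".join(gt.loci) + "\n")
        for i in range(gt.n_ind):
            for slot in (0, 1):
                vals = [
                    str(a) if (a := int(gt.alleles[i, j, slot])) != MISSING_ALLELE
                    else str(_STRUCTURE_MISSING)
                    for j in range(gt.n_loci)
                ]
                fh.write("\t".join([gt.individuals[i],
                                    str(pop_code[gt.populations[i]])] + vals) + "\n")


def read_structure(path) -> GenotypeTable:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    loci = lines[0].split()
    body = [ln.split() for ln in lines[1:]]
    if len(body) % 2:
        raise ValueError("odd number of genotype rows (expected 2 per individual)")
    individuals: list[str] = []
    pops: list[str] = []
    alleles = np.zeros((len(body) // 2, len(loci), 2), dtype=np.int64)
    for i in range(0, len(body), 2):
        r1, r2 = body[i], body[i + 1]
        if r1[0] != r2[0]:
            raise ValueError(f"row pair mismatch at individual {r1[0]!r}")
        individuals.append(r1[0])
        pops.append(f"pop{r1[1]}")
        for j in range(len(loci)):
            for slot, row in enumerate((r1, r2)):
                v = int(row[2 + j])
                alleles[i // 2, j, slot] = MISSING_ALLELE if v == _STRUCTURE_MISSING else v
    return GenotypeTable(alleles, individuals, np.array(pops, dtype=object), loci)


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: RasterGrid, path, nodata: float = -9999.0) -> None:
    v = np.where(np.isnan(grid.values), nodata, grid.values)
    header = (
        f"ncols {grid.ncol}\n"
        f"nrows {grid.nrow}\n"
        f"xllcorner {grid.west!r}\n"
        f"yllcorner {grid.south!r}\n"
        f"cellsize {grid.dx!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in v:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")


def read_ascii_grid(path, units: str = "") -> RasterGrid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.array(rows, dtype=float)
    if values.shape != (nrows, ncols):
        raise ValueError(f"grid body {values.shape} does not match header "
                         f"({nrows}, {ncols})")
    nodata = header.get("nodata_value", -9999.0)
    values[values == nodata] = np.nan
    cs = header["cellsize"]
    west, south = header["xllcorner"], header["yllcorner"]
    return RasterGrid(values, west, south, west + ncols * cs, south + nrows * cs,
                      units=units)


# ---------------------------------------------------------------------------
# dissimilarity matrix CSV
# ---------------------------------------------------------------------------

def write_dist_csv(d: DistMatrix, path) -> None:
    d.to_dataframe().to_csv(path, index_label="label")


def read_dist_csv(path, kind: str = "generic") -> DistMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DistMatrix(list(df.index), df.to_numpy(dtype=float), kind)
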