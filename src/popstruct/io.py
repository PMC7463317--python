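"""Readers and writers for SNP genotype panels.

Two plain-text formats are supported:

* the Genepop dialect used throughout population genetics (title line,
  locus names, ``POP`` blocks, two- or three-digit allele codes, all-zero
  code = missing), and
* a simple delimited table (one row per individual; columns ``id``,
  ``collection`` and one 0/1/2/NA column per locus).

Collection metadata (site, region, coordinates, date) reads from a
delimited file keyed by collection code.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, SampleCollection, SnpLocus

__all__ = [
    "GenepopParseError",
    "BiallelicViolationError",
    "read_genepop",
    "write_genepop",
    "read_table",
    "write_table",
    "read_collection_metadata",
    "write_collection_metadata",
]


class GenepopParseError(ValueError):
    """Malformed Genepop input; the message names the offending line."""


class BiallelicViolationError(ValueError):
    """More than two allele codes observed at a locus."""


_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _split_genotype_token(token: str, lineno: int) -> tuple[int, int]:
    """A Genepop genotype token is 4 (2+2) or 6 (3+3) digits."""
    if not token.isdigit() or len(token) not in (4, 6):
        raise GenepopParseError(f"line {lineno}: bad genotype token {token!r}")
    half = len(token) // 2
    return int(token[:half]), int(token[half:])


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Parse a Genepop file into a :class:`GenotypeMatrix`.

    POP blocks become collections. Within each locus the observed nonzero
    allele codes are mapped to the first/second allele by ascending
    numeric code; a zero half-code (0/00/000) is missing. A locus showing
    more than two distinct codes raises :class:`BiallelicViolationError`.

    Collection codes are inferred from individual identifiers: if every
    id in a block shares the prefix before the last underscore, that
    prefix is the code, otherwise the block gets ``POP<k>``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise GenepopParseError("line 1: empty file")
    # locus names: one per line until first POP, or one comma-separated line
    locus_names: list[str] = []
    i = 1
    first_pop = None
    for j in range(1, len(lines)):
        if _POP_RE.match(lines[j]):
            first_pop = j
            break
    if first_pop is None:
        raise GenepopParseError("line 2: no POP separator found")
    header_lines = [ln.strip() for ln in lines[1:first_pop] if ln.strip()]
    if not header_lines:
        raise GenepopParseError("line 2: no locus names before first POP")
    if len(header_lines) == 1 and "," in header_lines[0]:
        locus_names = [x.strip() for x in header_lines[0].split(",") if x.strip()]
    else:
        for ln in header_lines:
            if "," in ln:
                locus_names.extend(x.strip() for x in ln.split(",") if x.strip())
            else:
                locus_names.append(ln)
    L = len(locus_names)

    ids: list[str] = []
    pop_of: list[int] = []
    raw: list[list[tuple[int, int]]] = []
    pop_idx = -1
    for lineno0 in range(first_pop, len(lines)):
        line = lines[lineno0]
        lineno = lineno0 + 1
        if _POP_RE.match(line):
            pop_idx += 1
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise GenepopParseError(f"line {lineno}: expected 'id , genotypes'")
        ind_id, _, geno_part = line.partition(",")
        tokens = geno_part.split()
        if len(tokens) != L:
            raise GenepopParseError(
                f"line {lineno}: {len(tokens)} genotypes for {L} loci"
            )
        ids.append(ind_id.strip())
        pop_of.append(pop_idx)
        raw.append([_split_genotype_token(t, lineno) for t in tokens])

    n = len(ids)
    # per-locus code mapping, ascending numeric code
    calls = np.full((n, L), MISSING, dtype=np.int8)
    loci: list[SnpLocus] = []
    for j, name in enumerate(locus_names):
        codes = sorted(
            {a for row in raw for a in row[j] if a != 0}
        )
        if len(codes) > 2:
            raise BiallelicViolationError(
                f"locus {name}: {len(codes)} allele codes observed ({codes})"
            )
        if len(codes) == 0:
            alleles = ("?", "??")
            mono = True
        elif len(codes) == 1:
            alleles = (f"{codes[0]:03d}", "?")
            mono = True
        else:
            alleles = (f"{codes[0]:03d}", f"{codes[1]:03d}")
            mono = False
        loci.append(SnpLocus(locus_id=name, alleles=alleles, monomorphic=mono))
        if codes:
            second = codes[1] if len(codes) == 2 else None
            for i_row, row in enumerate(raw):
                a, b = row[j]
                if a == 0 or b == 0:
                    continue
                calls[i_row, j] = (a == second) + (b == second) if second else 0

    # collection codes from id prefixes
    codes_per_pop: list[str] = []
    for p in range(pop_idx + 1):
        members = [ids[i] for i in range(n) if pop_of[i] == p]
        prefixes = {m.rsplit("_", 1)[0] for m in members if "_" in m}
        if members and len(prefixes) == 1 and all("_" in m for m in members):
            codes_per_pop.append(prefixes.pop())
        else:
            codes_per_pop.append(f"POP{p + 1}")
    collection_codes = [codes_per_pop[p] for p in pop_of]
    return GenotypeMatrix(
        individuals=ids, collection_codes=collection_codes, loci=loci, calls=calls
    )


def write_genepop(gm: GenotypeMatrix, path: str | Path, title: str = "popstruct export") -> None:
    """Write a Genepop file: 3-digit codes, one POP block per collection.

    The first/second allele map to codes 001/002 and missing to 000000,
    so a write/read round trip reproduces the calls matrix exactly.
    """
    path = Path(path)
    out = [title]
    out.extend(gm.locus_ids)
    code_strings = {MISSING: "000000", 0: "001001", 1: "001002", 2: "002002"}
    for code in gm.collection_order():
        out.append("POP")
        for i in gm.indices_of(code):
            genos = " ".join(code_strings[int(g)] for g in gm.calls[i])
            out.append(f"{gm.individuals[i]} ,  {genos}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# delimited table format
# ---------------------------------------------------------------------------

def write_table(gm: GenotypeMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write the delimited genotype table (id, collection, loci as 0/1/2/NA).

    Allele symbols are preserved in a leading ``#alleles`` comment so the
    round trip is lossless.
    """
    path = Path(path)
    with open(path, "w") as fh:
        allele_spec = ",".join(
            f"{loc.locus_id}={loc.alleles[0]}/{loc.alleles[1]}" for loc in gm.loci
        )
        fh.write(f"#alleles{sep}{allele_spec}\n")
        fh.write(sep.join(["id", "collection", *gm.locus_ids]) + "\n")
        for i, ind in enumerate(gm.individuals):
            row = [ind, gm.collection_codes[i]]
            row.extend("NA" if g == MISSING else str(int(g)) for g in gm.calls[i])
            fh.write(sep.join(row) + "\n")


def read_table(path: str | Path, sep: str = "\t") -> GenotypeMatrix:
    """Read the delimited genotype table written by :func:`write_table`."""
    path = Path(path)
    allele_map: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#alleles"):
            spec = first.rstrip("\n").split(sep, 1)[1] if sep in first else ""
            for item in spec.split(","):
                if "=" in item:
                    lid, pair = item.split("=", 1)
                    a, _, b = pair.partition("/")
                    allele_map[lid] = (a, b)
            header = fh.readline().rstrip("\n").split(sep)
        else:
            header = first.rstrip("\n").split(sep)
        if header[:2] != ["id", "collection"]:
            raise ValueError(f"{path}: expected columns 'id' and 'collection' first")
        locus_names = header[2:]
        ids, codes, rows = [], [], []
        for lineno, line in enumerate(fh, start=3):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(sep)
            if len(parts) != len(header):
                raise ValueError(f"{path} line {lineno}: wrong column count")
            ids.append(parts[0])
            codes.append(parts[1])
            row = []
            for cell in parts[2:]:
                if cell == "NA":
                    row.append(MISSING)
                elif cell in ("0", "1", "2"):
                    row.append(int(cell))
                else:
                    raise ValueError(f"{path} line {lineno}: bad genotype {cell!r}")
            rows.append(row)
    calls = np.asarray(rows, dtype=np.int8) if rows else np.empty((0, len(locus_names)), np.int8)
    loci = [
        SnpLocus(locus_id=name, alleles=allele_map.get(name, ("A", "B")))
        for name in locus_names
    ]
    return GenotypeMatrix(individuals=ids, collection_codes=codes, loci=loci, calls=calls)


# ---------------------------------------------------------------------------
# collection metadata
# ---------------------------------------------------------------------------

_META_COLS = ["code", "region", "year", "month", "site", "latitude", "longitude", "ripe"]


def read_collection_metadata(path: str | Path, sep: str = "\t") -> dict[str, SampleCollection]:
    """Read site metadata (code, region, year, month, site, lat, lon, ripe)."""
    df = pd.read_csv(path, sep=sep)
    if "code" not in df.columns:
        raise ValueError(f"{path}: missing 'code' column")
    out: dict[str, SampleCollection] = {}
    for _, r in df.iterrows():
        code = str(r["code"])
        if code in out:
            raise ValueError(f"{path}: duplicate collection code {code!r}")
        out[code] = SampleCollection(
            code=code,
            region=str(r["region"]) if "region" in df.columns and pd.notna(r.get("region")) else None,
            latitude=float(r["latitude"]) if "latitude" in df.columns and pd.notna(r.get("latitude")) else None,
            longitude=float(r["longitude"]) if "longitude" in df.columns and pd.notna(r.get("longitude")) else None,
            year=int(r["year"]) if "year" in df.columns and pd.notna(r.get("year")) else None,
            month=int(r["month"]) if "month" in df.columns and pd.notna(r.get("month")) else None,
            site=str(r["site"]) if "site" in df.columns and pd.notna(r.get("site")) else None,
            ripe=bool(r["ripe"]) if "ripe" in df.columns and pd.notna(r.get("ripe")) else False,
        )
    return out


def write_collection_metadata(
    collections: Mapping[str, SampleCollection], path: str | Path, sep: str = "\t"
) -> None:
    rows = []
    for code, c in collections.items():
        rows.append(
            {
                "code": code,
                "region": c.region,
                "year": c.year,
                "month": c.month,
                "site": c.site,
                "latitude": c.latitude,
                "longitude": c.longitude,
                "ripe": c.ripe,
            }
        )
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep=sep, index=False)
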