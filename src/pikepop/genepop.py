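"""GENEPOP and CSV readers/writers for :class:`~pikepop.genotypes.GenotypeTable`.

GENEPOP layout: a free-text title line, one locus name per line (comma-
separated lists are accepted), then population blocks introduced by a line
reading ``POP`` (case-insensitive).  Each individual line is
``id , g1 g2 ...`` with fixed-width genotypes (two alleles of 2 or 3 digits
each); ``00``/``000`` encodes a missing allele.  Population labels follow
the GENEPOP convention of naming each block after its last individual id,
with an optional explicit override map (the override wins).
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeError, GenotypeTable, Locus


class GenepopParseError(GenotypeError):
    """Malformed GENEPOP input; message names the offending line."""


def _detect_width(dialect: str) -> int:
    if dialect not in ("2-digit", "3-digit"):
        raise ValueError("dialect must be '2-digit' or '3-digit'")
    return 2 if dialect == "2-digit" else 3


def read_genepop(
    path: str | Path | io.StringIO,
    dialect: str = "3-digit",
    pop_names: Mapping[int, str] | Sequence[str] | None = None,
) -> GenotypeTable:
    """Parse a GENEPOP file into a :class:`GenotypeTable`.

    Parameters
    ----------
    dialect : '2-digit' or '3-digit' allele encoding width.
    pop_names : optional override of population labels, by block index
        (mapping) or in file order (sequence); defaults to the last
        individual id of each block.
    """
    width = _detect_width(dialect)
    if isinstance(path, io.StringIO):
        lines = path.getvalue().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise GenepopParseError("file too short: missing title or locus names")
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        for tok in lines[i].split(","):
            tok = tok.strip()
            if tok:
                locus_names.append(tok)
        i += 1
    if len(set(locus_names)) != len(locus_names):
        raise GenepopParseError("duplicate locus names")
    if not locus_names:
        raise GenepopParseError("no locus names before first POP")

    blocks: list[list[tuple[str, list[tuple[int, int]]]]] = []
    while i < len(lines):
        assert lines[i].strip().upper() == "POP"
        i += 1
        block: list[tuple[str, list[tuple[int, int]]]] = []
        while i < len(lines) and lines[i].strip().upper() != "POP":
            line = lines[i]
            if line.strip():
                block.append(_parse_individual(line, i + 1, locus_names, width))
            i += 1
        if block:
            blocks.append(block)
    if not blocks:
        raise GenepopParseError("no POP blocks")

    # build registries from observed labels, ascending
    observed: list[set[int]] = [set() for _ in locus_names]
    for block in blocks:
        for _, genos in block:
            for j, (a, b) in enumerate(genos):
                if a != 0:
                    observed[j].add(a)
                if b != 0:
                    observed[j].add(b)
    loci = [Locus(n, tuple(sorted(obs))) for n, obs in zip(locus_names, observed)]

    ids: list[str] = []
    pops: list[str] = []
    calls_rows = []
    for bi, block in enumerate(blocks):
        label = block[-1][0]
        if pop_names is not None:
            if isinstance(pop_names, Mapping):
                label = pop_names.get(bi, label)
            elif bi < len(pop_names):
                label = pop_names[bi]
        for ind_id, genos in block:
            ids.append(ind_id)
            pops.append(label)
            row = np.full((len(loci), 2), MISSING, dtype=np.int32)
            for j, (a, b) in enumerate(genos):
                if a != 0 and b != 0:
                    row[j, 0] = loci[j].index_of(a)
                    row[j, 1] = loci[j].index_of(b)
            calls_rows.append(row)
    return GenotypeTable(ids, pops, loci, np.stack(calls_rows))


def _parse_individual(
    line: str, lineno: int, locus_names: list[str], width: int
) -> tuple[str, list[tuple[int, int]]]:
    if "," not in line:
        raise GenepopParseError(f"line {lineno}: missing ',' after individual id")
    ind_id, rest = line.split(",", 1)
    tokens = rest.split()
    if len(tokens) != len(locus_names):
        raise GenepopParseError(
            f"line {lineno}: {len(tokens)} genotypes for {len(locus_names)} loci"
        )
    genos: list[tuple[int, int]] = []
    for tok, name in zip(tokens, locus_names):
        if len(tok) != 2 * width or not tok.isdigit():
            raise GenepopParseError(
                f"line {lineno}: genotype {tok!r} at locus {name} is not "
                f"{2 * width} digits"
            )
        genos.append((int(tok[:width]), int(tok[width:])))
    return ind_id.strip(), genos


def write_genepop(
    table: GenotypeTable,
    path: str | Path | io.StringIO,
    dialect: str = "3-digit",
    title: str = "pikepop export",
) -> None:
    """Write a GENEPOP file (one locus name per line, POP-delimited blocks).

    The last individual of each block carries the population label as its id
    suffix convention is NOT imposed; ids are written verbatim, so tables
    whose last-per-block id equals the population label round-trip exactly.
    """
    width = _detect_width(dialect)
    if table.n_individuals == 0:
        raise GenotypeError("cannot write an empty table")
    for locus in table.loci:
        if locus.n_alleles > 10**width - 1:
            raise GenotypeError(
                f"locus {locus.name}: too many alleles for {dialect} encoding"
            )
        for a in locus.alleles:
            if not (1 <= a <= 10**width - 1):
                raise GenotypeError(
                    f"locus {locus.name}: allele label {a} not representable "
                    f"in {width} digits"
                )
    out: list[str] = [title]
    out.extend(l.name for l in table.loci)
    for pop in table.populations:
        out.append("POP")
        mask = table.pop_mask(pop)
        for i in np.flatnonzero(mask):
            cells = []
            for j, locus in enumerate(table.loci):
                lab = table.call_labels(i, j)
                if lab is None:
                    cells.append("0" * (2 * width))
                else:
                    cells.append(f"{lab[0]:0{width}d}{lab[1]:0{width}d}")
            out.append(f"{table.ids[i]} ,  " + " ".join(cells))
    text = "\n".join(out) + "\n"
    if isinstance(path, io.StringIO):
        path.write(text)
    else:
        Path(path).write_text(text)


# -- CSV dialect -----------------------------------------------------------


def read_csv(path: str | Path | io.StringIO) -> GenotypeTable:
    """Read the tabular dialect: columns ``id, population, <locus>:1, <locus>:2``.

    Empty cells or 0 encode a missing allele; half-calls normalise to missing.
    """
    df = pd.read_csv(path, dtype={"id": str, "population": str})
    if "id" not in df.columns or "population" not in df.columns:
        raise GenotypeError("CSV must have 'id' and 'population' columns")
    locus_names: list[str] = []
    for col in df.columns:
        if col.endswith(":1"):
            name = col[:-2]
            if f"{name}:2" not in df.columns:
                raise GenotypeError(f"missing column {name}:2")
            locus_names.append(name)
    if not locus_names:
        raise GenotypeError("no locus columns found")
    raw = np.zeros((len(df), len(locus_names), 2), dtype=np.int64)
    for j, name in enumerate(locus_names):
        for c in (1, 2):
            raw[:, j, c - 1] = (
                pd.to_numeric(df[f"{name}:{c}"], errors="coerce")
                .fillna(0)
                .astype(int)
                .to_numpy()
            )
    loci = []
    calls = np.full(raw.shape, MISSING, dtype=np.int32)
    for j, name in enumerate(locus_names):
        labels = tuple(sorted(set(raw[:, j, :][raw[:, j, :] > 0].tolist())))
        locus = Locus(name, labels)
        loci.append(locus)
        for c in range(2):
            col = raw[:, j, c]
            ok = col > 0
            lut = {a: k for k, a in enumerate(labels)}
            calls[ok, j, c] = [lut[v] for v in col[ok]]
    return GenotypeTable(df["id"].tolist(), df["population"].tolist(), loci, calls)


def write_csv(table: GenotypeTable, path: str | Path | io.StringIO) -> None:
    data: dict[str, list] = {"id": table.ids, "population": table.pops}
    for j, locus in enumerate(table.loci):
        c1, c2 = [], []
        for i in range(table.n_individuals):
            lab = table.call_labels(i, j)
            c1.append(lab[0] if lab else 0)
            c2.append(lab[1] if lab else 0)
        data[f"{locus.name}:1"] = c1
        data[f"{locus.name}:2"] = c2
    pd.DataFrame(data).to_csv(path, index=False)
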