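"""Data model and I/O for codominant microsatellite genotypes.

Alleles are integer fragment sizes in base pairs. A diploid genotype is an
unordered pair of alleles, held as a sorted ``(a, b)`` tuple, or ``None``
when the call is missing — a genotype is all-or-nothing missing; partial
calls are rejected at parse time.

Two interchange formats are supported: GENEPOP (3- or 2-digit allele
coding, one ``Pop`` block per colony) and a flat CSV with two columns per
locus. The genotypes of the 20 reference bee colonies (one inferred queen
per nest, 15 loci) and their nest coordinates ship with the package as
plain-text fixtures, together with a machine-readable curation log.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__

#: A diploid genotype: sorted (allele_a, allele_b) tuple, or None if missing.
Genotype = "tuple[int, int] | None"

MISSING: None = None


def genotype(a: int, b: int) -> tuple[int, int]:
    """Build an unordered diploid genotype from two allele sizes (bp)."""
    a, b = int(a), int(b)
    if a < 1 or b < 1:
        raise ValueError(f"allele sizes must be >= 1, got ({a}, {b})")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus: field name plus its 1-based SSR column index."""

    name: str
    ssr_index: int


@dataclass
class ColonyRecord:
    """One colony: id, planar nest coordinates (m) and sampled workers.

    ``workers`` is a list of per-worker genotype vectors, one genotype per
    locus (aligned with ``Dataset.loci``).
    """

    colony_id: str
    x: float = 0.0
    y: float = 0.0
    workers: list[list["tuple[int, int] | None"]] = field(default_factory=list)


@dataclass
class Dataset:
    """Loci definitions plus per-colony worker genotype matrices."""

    loci: list[LocusDef]
    colonies: list[ColonyRecord]

    def __post_init__(self) -> None:
        if not self.loci or not self.colonies:
            raise ValueError("dataset needs at least one locus and one colony")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        ids = [c.colony_id for c in self.colonies]
        if len(set(ids)) != len(ids):
            raise ValueError("colony ids must be unique")
        L = len(self.loci)
        for c in self.colonies:
            for w in c.workers:
                if len(w) != L:
                    raise ValueError(
                        f"colony {c.colony_id}: worker vector of length {len(w)}, expected {L}"
                    )

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def colony_ids(self) -> list[str]:
        return [c.colony_id for c in self.colonies]

    def colony(self, colony_id: str) -> ColonyRecord:
        for c in self.colonies:
            if c.colony_id == colony_id:
                return c
        raise KeyError(colony_id)

    def worker_genotypes_at(self, locus: str) -> "dict[str, list[tuple[int, int] | None]]":
        """Per-colony list of worker genotypes at one locus."""
        i = self.locus_names.index(locus)
        return {c.colony_id: [w[i] for w in c.workers] for c in self.colonies}

    def all_worker_genotypes_at(self, locus: str) -> "list[tuple[int, int] | None]":
        i = self.locus_names.index(locus)
        return [w[i] for c in self.colonies for w in c.workers]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# GENEPOP

_POP_RE = re.compile(r"^pop\s*$", re.IGNORECASE)


def _decode_genepop_pair(tok: str, width: int, line_no: int) -> "tuple[int, int] | None":
    if len(tok) != 2 * width or not tok.isdigit():
        raise ParseError(f"line {line_no}: bad allele code {tok!r} for {width}-digit coding")
    a, b = int(tok[:width]), int(tok[width:])
    if a == 0 and b == 0:
        return MISSING
    if a == 0 or b == 0:
        raise ParseError(f"line {line_no}: partial genotype {tok!r} (one allele missing)")
    return genotype(a, b)


def read_genepop(path: str | Path) -> Dataset:
    """Read a GENEPOP file; ``Pop`` blocks become colonies.

    Allele coding must be uniformly 2- or 3-digit; ``00``/``000`` codes a
    missing allele. The colony id is the label of the first individual of
    each block.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError("GENEPOP file too short")
    body = lines[1:]
    # locus names: either one per line until the first Pop, or comma-separated
    loci_names: list[str] = []
    i = 0
    while i < len(body) and not _POP_RE.match(body[i].strip()):
        loci_names.extend(t.strip() for t in body[i].split(",") if t.strip())
        i += 1
    if not loci_names:
        raise ParseError("no locus names before first Pop block")
    loci = [LocusDef(n, k + 1) for k, n in enumerate(loci_names)]
    colonies: list[ColonyRecord] = []
    width: int | None = None
    current: ColonyRecord | None = None
    for j in range(i, len(body)):
        line = body[j].strip()
        line_no = j + 2  # 1-based, counting the title line
        if not line:
            continue
        if _POP_RE.match(line):
            current = None
            continue
        if "," not in line:
            raise ParseError(f"line {line_no}: expected 'label , genotypes'")
        label, geno_part = line.split(",", 1)
        toks = geno_part.split()
        if len(toks) != len(loci):
            raise ParseError(
                f"line {line_no}: {len(toks)} genotypes for {len(loci)} loci"
            )
        w = len(toks[0]) // 2
        if w not in (2, 3):
            raise ParseError(f"line {line_no}: unsupported allele coding width")
        if width is None:
            width = w
        elif w != width:
            raise ParseError(f"line {line_no}: mixed 2- and 3-digit allele coding")
        row = [_decode_genepop_pair(t, width, line_no) for t in toks]
        if current is None:
            current = ColonyRecord(colony_id=label.strip())
            colonies.append(current)
        current.workers.append(row)
    if not colonies:
        raise ParseError("no Pop blocks found")
    return Dataset(loci=loci, colonies=colonies)


def write_genepop(dataset: Dataset, path: str | Path, title: str | None = None) -> None:
    """Write 3-digit GENEPOP; every individual is labelled with its colony id."""
    out = [title or f"nestkin {__version__} genotype export"]
    out.extend(l.name for l in dataset.loci)
    for c in dataset.colonies:
        out.append("Pop")
        for w in c.workers:
            toks = []
            for g in w:
                if g is MISSING:
                    toks.append("000000")
                else:
                    if g[1] > 999:
                        raise ValueError(f"allele {g[1]} exceeds 3-digit GENEPOP coding")
                    toks.append(f"{g[0]:03d}{g[1]:03d}")
            out.append(f"{c.colony_id} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV genotype tables

def read_csv_genotypes(path: str | Path) -> Dataset:
    """Read a two-columns-per-locus CSV genotype table.

    Header: ``colony_id, worker_id, <locus>.1, <locus>.2, ...``. Blank or
    ``0`` cells code a missing allele; both cells of a locus must agree on
    missingness. Rows with the same colony_id merge into one colony.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows:
        raise ParseError("empty CSV")
    header = rows[0]
    if len(header) < 4 or header[0] != "colony_id":
        raise ParseError("header must start with colony_id, worker_id, then allele columns")
    allele_cols = header[2:]
    if len(allele_cols) % 2:
        raise ParseError("odd number of allele columns")
    loci_names = []
    for k in range(0, len(allele_cols), 2):
        base1 = allele_cols[k].rsplit(".", 1)[0]
        base2 = allele_cols[k + 1].rsplit(".", 1)[0]
        if base1 != base2:
            raise ParseError(f"allele columns {allele_cols[k]!r}/{allele_cols[k+1]!r} do not pair")
        loci_names.append(base1)
    loci = [LocusDef(n, k + 1) for k, n in enumerate(loci_names)]
    colonies: dict[str, ColonyRecord] = {}
    for r_no, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(f"row {r_no}: {len(row)} fields, expected {len(header)}")
        cid = row[0]
        cells = row[2:]
        genos: list["tuple[int, int] | None"] = []
        for k in range(0, len(cells), 2):
            a_s, b_s = cells[k].strip(), cells[k + 1].strip()
            a = int(a_s) if a_s else 0
            b = int(b_s) if b_s else 0
            if a == 0 and b == 0:
                genos.append(MISSING)
            elif a == 0 or b == 0:
                raise ParseError(f"row {r_no}, locus {loci_names[k // 2]}: partial genotype")
            else:
                genos.append(genotype(a, b))
        colonies.setdefault(cid, ColonyRecord(colony_id=cid)).workers.append(genos)
    return Dataset(loci=loci, colonies=list(colonies.values()))


def write_csv_genotypes(dataset: Dataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# nestkin {__version__} genotype export\n")
        w = csv.writer(fh)
        header = ["colony_id", "worker_id"]
        for l in dataset.loci:
            header += [f"{l.name}.1", f"{l.name}.2"]
        w.writerow(header)
        for c in dataset.colonies:
            for i, wk in enumerate(c.workers, start=1):
                row = [c.colony_id, f"{c.colony_id}_w{i}"]
                for g in wk:
                    row += ["0", "0"] if g is MISSING else [str(g[0]), str(g[1])]
                w.writerow(row)


def read_coords_csv(path: str | Path) -> list[tuple[str, float, float]]:
    """Read colony coordinates CSV with columns nest/colony_id, x, y."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    header = [h.strip().lower() for h in rows[0]]
    id_col = 0
    xi, yi = header.index("x"), header.index("y")
    return [(r[id_col], float(r[xi]), float(r[yi])) for r in rows[1:]]


def attach_coordinates(dataset: Dataset, coords: Iterable[tuple[str, float, float]]) -> None:
    """Set colony coordinates in place from (colony_id, x, y) triples."""
    by_id = {cid: (x, y) for cid, x, y in coords}
    for c in dataset.colonies:
        if c.colony_id in by_id:
            c.x, c.y = by_id[c.colony_id]


# ---------------------------------------------------------------------------
# Packaged fixtures

def _data_text(name: str) -> str:
    return resources.files("nestkin").joinpath("data", name).read_text()


def curation_log() -> list[dict]:
    """Machine-readable log of curated cells in the queen-genotype fixture."""
    return json.loads(_data_text("curation.json"))


def load_fixture_queens(
    curated: bool = True,
) -> tuple[list[LocusDef], "dict[str, list[tuple[int, int] | None]]"]:
    """The packaged reference genotypes: 20 colony queens x 15 loci.

    Returns the loci (SSR order) and an ordered mapping colony_id -> list of
    15 diploid genotypes. With ``curated=True`` (default) the published
    typos listed in :func:`curation_log` are repaired; with ``curated=False``
    the affected cells are returned as missing and the raw strings are left
    to the log.
    """
    lines = [l for l in _data_text("queen_genotypes.csv").splitlines() if not l.startswith("#")]
    header = lines[0].split(",")
    loci = [LocusDef(n, k + 1) for k, n in enumerate(header[1:])]
    fixes = {(e["nest"], e["locus"]): e["curated"] for e in curation_log()}
    queens: dict[str, list["tuple[int, int] | None"]] = {}
    for line in lines[1:]:
        parts = line.split(",")
        nest = parts[0]
        row: list["tuple[int, int] | None"] = []
        for locus, cell in zip((l.name for l in loci), parts[1:]):
            if (nest, locus) in fixes:
                cell = fixes[(nest, locus)] if curated else ""
            if not cell:
                row.append(MISSING)
                continue
            a, b = cell.split("/")
            row.append(genotype(int(a), int(b)))
        queens[nest] = row
    return loci, queens


def load_fixture_coords() -> list[tuple[str, float, float]]:
    """Packaged nest coordinates: 20 (colony_id, easting, northing) in metres."""
    lines = [l for l in _data_text("nest_coordinates.csv").splitlines() if not l.startswith("#")]
    out = []
    for line in lines[1:]:
        nest, x, y, _ = line.split(",")
        out.append((nest, float(x), float(y)))
    return out


def queens_as_dataset(
    loci: Sequence[LocusDef], queens: "dict[str, list[tuple[int, int] | None]]"
) -> Dataset:
    """View a queen-genotype matrix as a Dataset with one 'worker' per colony.

    Convenient for running Dataset-shaped stages (HWE, export) directly on
    queen genotypes.
    """
    cols = [ColonyRecord(colony_id=cid, workers=[list(g)]) for cid, g in queens.items()]
    return Dataset(loci=list(loci), colonies=cols)
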