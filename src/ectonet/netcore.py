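"""Data model, I/O and cohort assembly for individual-based bipartite networks.

A network here is one host species in one region crossed with one parasite
group (fleas or mites): rows are individual hosts, columns are parasite
species, and entries are counts of parasite individuals.  Hosts carrying no
parasite of the focal group are excluded (every position index is undefined
for an isolated node), and a network is retained only if it still holds at
least ``min_per_sex`` parasitized females and males.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SEX_MAP = {"f": "F", "female": "F", "m": "M", "male": "M"}

REQUIRED_COLUMNS = ("host_id", "species", "region", "site", "sex", "parasite", "count")


class SchemaError(ValueError):
    """Input file does not conform to the expected column schema."""


@dataclass(frozen=True)
class HostRecord:
    """Metadata for one captured host individual."""

    host_id: str
    species: str
    region: str
    site: str
    sex: str  # "F" or "M"

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")


@dataclass
class InteractionMatrix:
    """Hosts x parasites count matrix with aligned labels.

    Invariants enforced at construction: integer counts >= 0, no all-zero
    row or column, at least 2 rows and 1 column, grand total >= 1.
    """

    counts: np.ndarray
    host_ids: list[str]
    parasites: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        n, s = self.counts.shape
        if n < 2 or s < 1:
            raise ValueError(f"matrix must have >=2 hosts and >=1 parasite, got {n}x{s}")
        if len(self.host_ids) != n or len(self.parasites) != s:
            raise ValueError("label lengths do not match matrix shape")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("all-zero host row present")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError("all-zero parasite column present")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.host_ids, columns=self.parasites)


@dataclass
class Marginals:
    """Row/column totals and fill statistics of an interaction matrix."""

    A_i: np.ndarray  # per-host parasite totals
    A_j: np.ndarray  # per-parasite host totals
    m: int  # grand total
    L: int  # number of nonzero cells
    connectance: float


@dataclass
class NetworkBundle:
    """One individual-based network with aligned host metadata."""

    matrix: InteractionMatrix
    hosts: list[HostRecord]
    parasite_group: str
    id: str

    def __post_init__(self) -> None:
        if len(self.hosts) != self.matrix.shape[0]:
            raise ValueError("host records not aligned to matrix rows")
        for rec, hid in zip(self.hosts, self.matrix.host_ids):
            if rec.host_id != hid:
                raise ValueError(f"host order mismatch: {rec.host_id} vs {hid}")
        species = {h.species for h in self.hosts}
        regions = {h.region for h in self.hosts}
        if len(species) != 1 or len(regions) != 1:
            raise ValueError("all hosts in a bundle must share species and region")

    @property
    def species(self) -> str:
        return self.hosts[0].species

    @property
    def region(self) -> str:
        return self.hosts[0].region

    @property
    def sexes(self) -> np.ndarray:
        return np.array([h.sex for h in self.hosts])


def _normalize_sex(raw: str, line_no: int) -> str:
    key = raw.strip().lower()
    if key not in _SEX_MAP:
        raise ValueError(f"line {line_no}: sex {raw!r} not in F/M/female/male")
    return _SEX_MAP[key]


def read_records(
    path: str | Path, dialect: str = "csv"
) -> tuple[list[HostRecord], list[tuple[str, str, str, int]]]:
    """Read a long-format host-parasite table.

    Expected columns: host_id, species, region, site, sex, parasite, count,
    one row per (host, parasite group member, count) observation.

    Returns ``(records, triples)`` where each triple is
    ``(host_id, parasite_group, parasite, count)``.  The parasite group is
    inferred from an optional ``group`` column; when absent every parasite
    belongs to the single group ``"parasite"``.  Zero counts are dropped with
    a warning; duplicated (host, parasite) rows are summed.
    """
    delim = {"csv": ",", "tsv": "\t"}.get(dialect)
    if delim is None:
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    path = Path(path)
    records: dict[str, HostRecord] = {}
    agg: dict[tuple[str, str, str], int] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        has_group = "group" in header
        for line_no, row in enumerate(reader, start=2):
            sex = _normalize_sex(row["sex"], line_no)
            rec = HostRecord(
                host_id=row["host_id"].strip(),
                species=row["species"].strip(),
                region=row["region"].strip(),
                site=row["site"].strip(),
                sex=sex,
            )
            prev = records.get(rec.host_id)
            if prev is None:
                records[rec.host_id] = rec
            elif prev != rec:
                raise ValueError(
                    f"line {line_no}: host {rec.host_id} has conflicting metadata"
                )
            raw_count = row["count"].strip()
            try:
                count = int(raw_count)
            except ValueError as exc:
                raise ValueError(
                    f"line {line_no}: count {raw_count!r} is not an integer"
                ) from exc
            if count < 0:
                raise ValueError(f"line {line_no}: negative count {count}")
            if count == 0:
                logger.warning("line %d: zero count dropped (%s)", line_no, rec.host_id)
                continue
            group = row["group"].strip() if has_group else "parasite"
            key = (rec.host_id, group, row["parasite"].strip())
            if key in agg:
                logger.warning(
                    "line %d: duplicate (host, parasite) %s summed", line_no, key
                )
            agg[key] = agg.get(key, 0) + count
    triples = [(h, g, p, c) for (h, g, p), c in sorted(agg.items())]
    return list(records.values()), triples


def write_records(
    path: str | Path,
    records: Sequence[HostRecord],
    triples: Iterable[tuple[str, str, str, int]],
    dialect: str = "csv",
) -> None:
    """Write records/triples back to the long format read by :func:`read_records`."""
    delim = {"csv": ",", "tsv": "\t"}[dialect]
    by_id = {r.host_id: r for r in records}
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(list(REQUIRED_COLUMNS) + ["group"])
        for host_id, group, parasite, count in triples:
            r = by_id[host_id]
            writer.writerow(
                [r.host_id, r.species, r.region, r.site, r.sex, parasite, count, group]
            )


def build_networks(
    records: Sequence[HostRecord],
    triples: Iterable[tuple[str, str, str, int]],
    min_per_sex: int = 20,
) -> list[NetworkBundle]:
    """Assemble one bundle per (species, region, parasite group).

    Hosts with zero parasites of the focal group are excluded before the
    ``min_per_sex`` filter is applied, so the filter counts parasitized
    individuals only; bundles failing it are dropped and logged.
    """
    by_id = {r.host_id: r for r in records}
    cells: dict[tuple[str, str, str], dict[tuple[str, str], int]] = {}
    for host_id, group, parasite, count in triples:
        rec = by_id.get(host_id)
        if rec is None:
            raise ValueError(f"triple references unknown host_id {host_id!r}")
        key = (rec.species, rec.region, group)
        cells.setdefault(key, {})[(host_id, parasite)] = (
            cells.get(key, {}).get((host_id, parasite), 0) + count
        )

    bundles: list[NetworkBundle] = []
    for (species, region, group), cell_map in sorted(cells.items()):
        host_ids = sorted({h for h, _ in cell_map})
        parasites = sorted({p for _, p in cell_map})
        mat = np.zeros((len(host_ids), len(parasites)), dtype=np.int64)
        hidx = {h: i for i, h in enumerate(host_ids)}
        pidx = {p: j for j, p in enumerate(parasites)}
        for (h, p), c in cell_map.items():
            mat[hidx[h], pidx[p]] += c
        # zero rows/columns cannot occur (triples have count >= 1), but a
        # host may appear only under the other parasite group
        hosts = [by_id[h] for h in host_ids]
        n_f = sum(1 for h in hosts if h.sex == "F")
        n_m = sum(1 for h in hosts if h.sex == "M")
        bundle_id = f"{species}|{region}|{group}"
        if n_f < min_per_sex or n_m < min_per_sex:
            logger.info(
                "dropping %s: %d F / %d M parasitized (< %d per sex)",
                bundle_id,
                n_f,
                n_m,
                min_per_sex,
            )
            continue
        matrix = InteractionMatrix(mat, host_ids, parasites)
        bundles.append(
            NetworkBundle(matrix=matrix, hosts=hosts, parasite_group=group, id=bundle_id)
        )
    if not bundles:
        logger.info("no bundle satisfied the min_per_sex=%d filter", min_per_sex)
    return bundles


def marginals(matrix: InteractionMatrix) -> Marginals:
    """Row/column totals, grand total, fill and connectance."""
    a = matrix.counts
    A_i = a.sum(axis=1)
    A_j = a.sum(axis=0)
    m = int(a.sum())
    L = int((a > 0).sum())
    return Marginals(
        A_i=A_i, A_j=A_j, m=m, L=L, connectance=L / (a.shape[0] * a.shape[1])
    )


def to_binary(matrix: InteractionMatrix | np.ndarray) -> np.ndarray:
    """Presence/absence (0/1) version of a count matrix."""
    a = matrix.counts if isinstance(matrix, InteractionMatrix) else np.asarray(matrix)
    return (a > 0).astype(np.int64)


def save_bundles(bundles: Sequence[NetworkBundle], outdir: str | Path) -> None:
    """Serialize bundles to a directory of CSV matrices plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for b in bundles:
        stem = b.id.replace("|", "_").replace(" ", "_").replace("/", "_")
        b.matrix.to_frame().to_csv(outdir / f"{stem}.matrix.csv")
        meta = pd.DataFrame(
            [
                {
                    "host_id": h.host_id,
                    "species": h.species,
                    "region": h.region,
                    "site": h.site,
                    "sex": h.sex,
                }
                for h in b.hosts
            ]
        )
        meta.to_csv(outdir / f"{stem}.hosts.csv", index=False)
        manifest.append(
            {
                "id": b.id,
                "species": b.species,
                "region": b.region,
                "parasite_group": b.parasite_group,
                "n_hosts": b.matrix.shape[0],
                "n_parasites": b.matrix.shape[1],
                "matrix": f"{stem}.matrix.csv",
                "hosts": f"{stem}.hosts.csv",
            }
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_bundles(indir: str | Path) -> list[NetworkBundle]:
    """Load bundles previously written by :func:`save_bundles`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    bundles = []
    for entry in manifest:
        mat = pd.read_csv(indir / entry["matrix"], index_col=0)
        meta = pd.read_csv(indir / entry["hosts"], dtype=str)
        hosts = [HostRecord(**row) for row in meta.to_dict("records")]
        matrix = InteractionMatrix(
            mat.to_numpy(), [str(i) for i in mat.index], list(mat.columns)
        )
        bundles.append(
            NetworkBundle(
                matrix=matrix,
                hosts=hosts,
                parasite_group=entry["parasite_group"],
                id=entry["id"],
            )
        )
    return bundles
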