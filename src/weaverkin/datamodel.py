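"""Core data model, validation and delimited-text I/O.

The analysis consumes five delimited tables (CSV or TSV, sniffed from the
extension):

``individuals.csv``
    ``id, sex, colony_id, age_years, is_builder`` — one row per bird.
``genotypes.csv``
    Long format: ``id, locus, allele1, allele2`` — one row per (bird, locus).
    Missing calls are empty fields (``0`` and ``-9`` are accepted on input
    and normalised to missing).
``chambers.csv``
    ``colony_id, chamber_id, x, y`` — planar chamber coordinates, unitless.
``observations.csv``
    ``bird_id, colony_id, chamber_id, series_id, activity`` — one row per
    chamber entry; ``activity`` is ``roost`` or ``chamber_build``.
``building.csv``
    ``bird_id, colony_id, location_chamber_id, count`` — thatch-building
    events aggregated by the chamber directly beneath the building location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SEXES",
    "ACTIVITIES",
    "MISSING_ALLELE_SENTINELS",
    "DataValidationError",
    "Individual",
    "GenotypeTable",
    "ChamberMap",
    "ObservationLog",
    "ColonyDataset",
    "read_dataset",
    "write_dataset",
    "export_network",
]

SEXES = ("male", "female", "unknown")
ACTIVITIES = ("roost", "chamber_build")
#: allele strings normalised to "missing" on input
MISSING_ALLELE_SENTINELS = {"", "0", "-9", "na", "nan", "none"}


class DataValidationError(ValueError):
    """Input data violated a structural or referential constraint.

    ``code`` is a stable machine-readable identifier; ``rows`` carries the
    offending row numbers (0-based, data rows) where known.
    """

    def __init__(self, code: str, message: str, rows: Sequence[int] = ()):
        super().__init__(f"[{code}] {message}")
        self.code = code
        self.rows = list(rows)


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str = "unknown"
    colony_id: str = ""
    age_years: float | None = None
    is_builder: bool | None = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise DataValidationError(
                "bad_sex", f"individual {self.id!r}: sex {self.sex!r} not in {SEXES}"
            )
        if self.age_years is not None and self.age_years < 0:
            raise DataValidationError(
                "bad_age", f"individual {self.id!r}: negative age {self.age_years}"
            )


class GenotypeTable:
    """Diploid codominant genotypes for a set of individuals.

    Allele labels are opaque strings; internally they are integer-coded per
    locus (``-1`` marks a missing call).  A call is either fully missing or
    carries exactly two allele labels.
    """

    def __init__(
        self,
        ids: Sequence[str],
        loci: Sequence[str],
        codes: np.ndarray,
        allele_labels: Sequence[Sequence[str]],
    ):
        self.ids = list(ids)
        self.loci = list(loci)
        codes = np.asarray(codes, dtype=np.int32)
        if codes.shape != (len(self.ids), len(self.loci), 2):
            raise DataValidationError(
                "bad_shape",
                f"genotype code array shape {codes.shape} != "
                f"({len(self.ids)}, {len(self.loci)}, 2)",
            )
        # a call is missing iff both positions are -1
        half = (codes == -1).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise DataValidationError(
                "half_call",
                f"individual {self.ids[i]!r}, locus {self.loci[l]!r}: "
                "call has exactly one allele; need two or none",
            )
        self.codes = codes
        self.allele_labels = [list(a) for a in allele_labels]
        self._index = {b: i for i, b in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise DataValidationError("dup_id", "duplicate individual ids in genotype table")
        if len(self.loci) < 1:
            raise DataValidationError("no_loci", "genotype table needs at least one locus")

    @classmethod
    def from_calls(
        cls,
        calls: Mapping[str, Mapping[str, tuple[str, str] | None]],
        loci: Sequence[str] | None = None,
    ) -> "GenotypeTable":
        """Build from ``{individual: {locus: (a1, a2) or None}}``."""
        ids = list(calls)
        if loci is None:
            loci = sorted({l for g in calls.values() for l in g})
        loci = list(loci)
        label_maps: list[dict[str, int]] = [{} for _ in loci]
        codes = np.full((len(ids), len(loci), 2), -1, dtype=np.int32)
        for i, b in enumerate(ids):
            for j, l in enumerate(loci):
                pair = calls[b].get(l)
                if pair is None:
                    continue
                a1, a2 = (str(a) for a in pair)
                for s, a in enumerate((a1, a2)):
                    codes[i, j, s] = label_maps[j].setdefault(a, len(label_maps[j]))
        labels = [sorted(m, key=m.get) for m in label_maps]
        return cls(ids, loci, codes, labels)

    def subset(self, ids: Sequence[str]) -> "GenotypeTable":
        idx = [self._index[b] for b in ids]
        return GenotypeTable(list(ids), self.loci, self.codes[idx], self.allele_labels)

    def call(self, individual: str, locus: str) -> tuple[str, str] | None:
        i = self._index[individual]
        j = self.loci.index(locus)
        c = self.codes[i, j]
        if c[0] < 0:
            return None
        lab = self.allele_labels[j]
        return (lab[c[0]], lab[c[1]])

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is missing."""
        return self.codes[:, :, 0] < 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.ids):
            for j, l in enumerate(self.loci):
                c = self.codes[i, j]
                if c[0] < 0:
                    rows.append((b, l, "", ""))
                else:
                    lab = self.allele_labels[j]
                    rows.append((b, l, lab[c[0]], lab[c[1]]))
        return pd.DataFrame(rows, columns=["id", "locus", "allele1", "allele2"])

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        if self.ids != other.ids or self.loci != other.loci:
            return False
        # compare label-decoded calls (codes may differ by label permutation)
        for j in range(self.n_loci):
            a = np.asarray(self.allele_labels[j] + [""], dtype=object)[self.codes[:, j]]
            b = np.asarray(other.allele_labels[j] + [""], dtype=object)[other.codes[:, j]]
            if not (np.sort(a, axis=1) == np.sort(b, axis=1)).all():
                return False
        return True


@dataclass
class ChamberMap:
    """Planar coordinates of one colony's nest chambers (unitless)."""

    colony_id: str
    chambers: dict[str, tuple[float, float]]

    def __post_init__(self):
        for cid, (x, y) in self.chambers.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise DataValidationError(
                    "bad_coord", f"colony {self.colony_id!r} chamber {cid!r}: non-finite coordinate"
                )

    @property
    def ids(self) -> list[str]:
        return list(self.chambers)

    def coords(self) -> np.ndarray:
        return np.array([self.chambers[c] for c in self.chambers], dtype=float)


@dataclass
class ObservationLog:
    """Chamber-entry records and thatch-building events.

    ``entries`` rows: (bird_id, colony_id, chamber_id, series_id, activity).
    ``building_events`` rows: (bird_id, colony_id, location_chamber_id, count)
    where the location chamber is the one directly beneath the thatch site.
    """

    entries: pd.DataFrame
    building_events: pd.DataFrame

    ENTRY_COLS = ["bird_id", "colony_id", "chamber_id", "series_id", "activity"]
    BUILD_COLS = ["bird_id", "colony_id", "location_chamber_id", "count"]

    def __post_init__(self):
        self.entries = pd.DataFrame(self.entries, columns=self.ENTRY_COLS).astype(
            {c: str for c in self.ENTRY_COLS}
        )
        self.building_events = pd.DataFrame(
            self.building_events, columns=self.BUILD_COLS
        ).astype({"bird_id": str, "colony_id": str, "location_chamber_id": str, "count": int})
        bad = ~self.entries["activity"].isin(ACTIVITIES)
        if bad.any():
            raise DataValidationError(
                "bad_activity",
                f"unknown activity values {sorted(self.entries.loc[bad, 'activity'].unique())}; "
                f"expected one of {ACTIVITIES}",
                rows=list(np.flatnonzero(bad.to_numpy())),
            )
        if (self.building_events["count"] < 1).any():
            bad_rows = np.flatnonzero((self.building_events["count"] < 1).to_numpy())
            raise DataValidationError(
                "bad_count", "building event counts must be >= 1", rows=list(bad_rows)
            )

    def for_colony(self, colony_id: str, series_id: str | None = None) -> "ObservationLog":
        e = self.entries[self.entries["colony_id"] == colony_id]
        if series_id is not None:
            e = e[e["series_id"] == series_id]
        b = self.building_events[self.building_events["colony_id"] == colony_id]
        return ObservationLog(e.reset_index(drop=True), b.reset_index(drop=True))


@dataclass
class ColonyDataset:
    """A complete analysis input: birds, genotypes, chambers, observations."""

    individuals: list[Individual]
    genotypes: GenotypeTable
    chamber_maps: dict[str, ChamberMap]
    observations: ObservationLog
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [b.id for b in self.individuals]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError("dup_id", f"duplicate individual ids: {dups}")
        self.validate_crossrefs()

    def validate_crossrefs(self) -> None:
        known_birds = {b.id for b in self.individuals}
        stray = set(self.genotypes.ids) - known_birds
        if stray:
            raise DataValidationError(
                "unknown_bird", f"genotyped birds absent from individuals table: {sorted(stray)}"
            )
        chambers = {
            (m.colony_id, c) for m in self.chamber_maps.values() for c in m.chambers
        }
        obs = self.observations
        for df, col, what in (
            (obs.entries, "chamber_id", "observation"),
            (obs.building_events, "location_chamber_id", "building event"),
        ):
            pairs = list(zip(df["colony_id"], df[col]))
            bad = [i for i, p in enumerate(pairs) if p not in chambers]
            if bad:
                offender = pairs[bad[0]]
                raise DataValidationError(
                    "unknown_chamber",
                    f"{what} rows reference chambers missing from the chamber map, "
                    f"e.g. row {bad[0]}: colony {offender[0]!r} chamber {offender[1]!r} "
                    f"({len(bad)} offending rows)",
                    rows=bad,
                )
        for df, what in ((obs.entries, "observation"), (obs.building_events, "building event")):
            bad = [i for i, b in enumerate(df["bird_id"]) if b not in known_birds]
            if bad:
                raise DataValidationError(
                    "unknown_bird",
                    f"{what} rows reference birds missing from the individuals table, "
                    f"e.g. row {bad[0]}: bird {df['bird_id'].iloc[bad[0]]!r} "
                    f"({len(bad)} offending rows)",
                    rows=bad,
                )

    @property
    def colony_ids(self) -> list[str]:
        return sorted({b.colony_id for b in self.individuals})

    def individuals_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [b.id for b in self.individuals],
                "sex": [b.sex for b in self.individuals],
                "colony_id": [b.colony_id for b in self.individuals],
                "age_years": [b.age_years for b in self.individuals],
                "is_builder": [b.is_builder for b in self.individuals],
            }
        )

    def by_id(self) -> dict[str, Individual]:
        return {b.id: b for b in self.individuals}


# ---------------------------------------------------------------------------
# Readers / writers


def _read_table(path: Path, required: Sequence[str]) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(
            "missing_column", f"{path.name}: required columns absent: {missing}"
        )
    return df


def _norm_allele(a: str) -> str | None:
    a = str(a).strip()
    return None if a.lower() in MISSING_ALLELE_SENTINELS else a


def read_dataset(paths: Mapping[str, str | Path], config: Mapping | None = None) -> ColonyDataset:
    """Read and validate a dataset from its five delimited tables.

    ``paths`` maps the keys ``individuals``, ``genotypes``, ``chambers``,
    ``observations``, ``building`` to file paths.  Referential-integrity
    violations raise :class:`DataValidationError` naming the offending rows.
    """
    paths = {k: Path(v) for k, v in paths.items()}
    for key in ("individuals", "genotypes", "chambers", "observations", "building"):
        if key not in paths:
            raise DataValidationError("missing_file", f"no path given for {key!r} table")
        if not paths[key].exists():
            raise DataValidationError("missing_file", f"{paths[key]} does not exist")

    ind_df = _read_table(paths["individuals"], ["id", "sex", "colony_id"])
    individuals = []
    for _, row in ind_df.iterrows():
        age = row.get("age_years", "")
        builder = str(row.get("is_builder", "")).strip().lower()
        individuals.append(
            Individual(
                id=str(row["id"]),
                sex=str(row["sex"]).strip().lower() or "unknown",
                colony_id=str(row["colony_id"]),
                age_years=float(age) if str(age).strip() else None,
                is_builder={"true": True, "1": True, "false": False, "0": False}.get(builder),
            )
        )

    gdf = _read_table(paths["genotypes"], ["id", "locus", "allele1", "allele2"])
    calls: dict[str, dict[str, tuple[str, str] | None]] = {}
    loci_order: list[str] = []
    for i, row in gdf.iterrows():
        a1, a2 = _norm_allele(row["allele1"]), _norm_allele(row["allele2"])
        if (a1 is None) != (a2 is None):
            raise DataValidationError(
                "half_call",
                f"genotypes row {i}: bird {row['id']!r} locus {row['locus']!r} "
                "has one allele present and one missing",
                rows=[i],
            )
        locus = str(row["locus"])
        if locus not in loci_order:
            loci_order.append(locus)
        calls.setdefault(str(row["id"]), {})[locus] = None if a1 is None else (a1, a2)
    genotypes = GenotypeTable.from_calls(calls, loci=loci_order)

    cdf = _read_table(paths["chambers"], ["colony_id", "chamber_id", "x", "y"])
    chamber_maps: dict[str, ChamberMap] = {}
    for colony, grp in cdf.groupby("colony_id", sort=True):
        if grp["chamber_id"].duplicated().any():
            dups = sorted(grp.loc[grp["chamber_id"].duplicated(), "chamber_id"])
            raise DataValidationError(
                "dup_chamber", f"colony {colony!r}: duplicate chamber ids {dups}"
            )
        chamber_maps[str(colony)] = ChamberMap(
            str(colony),
            {str(r["chamber_id"]): (float(r["x"]), float(r["y"])) for _, r in grp.iterrows()},
        )

    odf = _read_table(paths["observations"], ObservationLog.ENTRY_COLS)
    bdf = _read_table(paths["building"], ObservationLog.BUILD_COLS)
    obs = ObservationLog(odf, bdf)

    return ColonyDataset(individuals, genotypes, chamber_maps, obs, provenance={"source": "files"})


def write_dataset(dataset: ColonyDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the five tables; returns the path of each file written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{k}.csv" for k in
             ("individuals", "genotypes", "chambers", "observations", "building")}
    ind = dataset.individuals_frame()
    ind["age_years"] = ind["age_years"].map(lambda v: "" if v is None or pd.isna(v) else v)
    ind["is_builder"] = ind["is_builder"].map(
        lambda v: "" if v is None or (isinstance(v, float) and pd.isna(v)) else str(bool(v)).lower()
    )
    ind.to_csv(paths["individuals"], index=False)
    dataset.genotypes.to_frame().to_csv(paths["genotypes"], index=False)
    rows = [
        (m.colony_id, c, x, y)
        for m in dataset.chamber_maps.values()
        for c, (x, y) in m.chambers.items()
    ]
    pd.DataFrame(rows, columns=["colony_id", "chamber_id", "x", "y"]).to_csv(
        paths["chambers"], index=False
    )
    dataset.observations.entries.to_csv(paths["observations"], index=False)
    dataset.observations.building_events.to_csv(paths["building"], index=False)
    return paths


def export_network(net, path: str | Path, format: str = "edge_list") -> Path:
    """Export an association network as a weighted edge list (TSV) or GraphML.

    Node attributes (sex, builder status, partition id) survive the GraphML
    round trip; the edge list carries ``id1, id2, weight`` rows.
    """
    path = Path(path)
    g = net.graph if hasattr(net, "graph") else net
    if g.number_of_nodes() == 0:
        warnings.warn(f"exporting empty network to {path}", stacklevel=2)
    if format == "edge_list":
        with open(path, "w") as fh:
            fh.write("id1\tid2\tweight\n")
            for u, v, w in sorted(g.edges(data="weight", default=1.0)):
                fh.write(f"{u}\t{v}\t{w}\n")
    elif format == "graphml":
        h = nx.Graph()
        for n, attrs in g.nodes(data=True):
            h.add_node(n, **{k: v for k, v in attrs.items() if v is not None})
        for u, v, attrs in g.edges(data=True):
            h.add_edge(u, v, **attrs)
        nx.write_graphml(h, path)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path
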