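"""Domain types and tabular I/O.

The model works on four kinds of input, all plain delimited text:

* binary alteration tables (cell lines x genes), one for somatic mutation
  status and one for copy-number-alteration status;
* a drug-response table (cell lines x drugs) of IC50-scale sensitivities,
  blanks/NA allowed;
* a drug panel mapping drug id/name to target gene symbols;
* an optional directed pathway edge list (gene -> gene) for the topology
  prior.

Binarization of raw variant / copy-number calls happens upstream: the
readers here accept tables whose entries are already 0/1.  Sensitivities
are used on whatever scale the input provides; no transform is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlterationProfile",
    "ResponseTable",
    "DrugRecord",
    "DrugPanel",
    "PathwayGraph",
    "ModelParameters",
    "read_alteration_tables",
    "read_response_table",
    "read_drug_panel",
    "read_pathway_edges",
    "write_alteration_tables",
    "write_response_table",
    "write_pathway_edges",
]


def _infer_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlterationProfile:
    """Binary mutation matrix ``m`` and copy-number matrix ``v`` over
    (sample, gene).

    Both matrices have shape ``(len(samples), len(genes))`` and entries in
    {0, 1}; copy-number gain and loss are collapsed to a single indicator
    because the model has one copy-number coefficient per gene.
    """

    samples: tuple[str, ...]
    genes: tuple[str, ...]
    m: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=np.int8)
        v = np.asarray(self.v, dtype=np.int8)
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "v", v)
        shape = (len(self.samples), len(self.genes))
        if m.shape != shape or v.shape != shape:
            raise ValueError(
                f"matrix shapes {m.shape}/{v.shape} do not match "
                f"(samples, genes) = {shape}"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        for name, mat in (("mutation", m), ("copy-number", v)):
            bad = ~np.isin(mat, (0, 1))
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise ValueError(
                    f"non-binary entry {mat[r, c]} in {name} matrix at "
                    f"sample {self.samples[r]!r}, gene {self.genes[c]!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def row(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        """Return the (m, v) gene vectors of one cell line."""
        try:
            i = self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None
        return self.m[i], self.v[i]


@dataclass(frozen=True)
class ResponseTable:
    """Observed drug sensitivities (IC50 scale) with a missingness mask.

    ``sens`` has shape (samples, drugs); ``observed`` is 1 where a
    measurement exists.  ``sens`` is NaN exactly where ``observed`` is 0.
    """

    samples: tuple[str, ...]
    drugs: tuple[str, ...]
    sens: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        sens = np.asarray(self.sens, dtype=float)
        observed = np.asarray(self.observed, dtype=bool)
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "sens", sens)
        object.__setattr__(self, "observed", observed)
        shape = (len(self.samples), len(self.drugs))
        if sens.shape != shape or observed.shape != shape:
            raise ValueError("sens/observed shape mismatch")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.drugs)) != len(self.drugs):
            raise ValueError("duplicate drug identifiers")
        if not np.isfinite(sens[observed]).all():
            raise ValueError("non-finite sensitivity marked as observed")

    @classmethod
    def from_matrix(
        cls, samples: Sequence[str], drugs: Sequence[str], sens: np.ndarray
    ) -> "ResponseTable":
        """Build from a matrix where missing entries are NaN."""
        sens = np.asarray(sens, dtype=float)
        observed = np.isfinite(sens)
        sens = np.where(observed, sens, np.nan)
        return cls(tuple(samples), tuple(drugs), sens, observed)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str
    targets: frozenset[str]


@dataclass(frozen=True)
class DrugPanel:
    """A drug panel: per drug an identifier, a name and a target gene set.

    Targets are consumed only by the topology prior; the fitted model
    treats every (gene, drug) influence coefficient as free.
    """

    drugs: tuple[DrugRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", tuple(self.drugs))
        ids = [d.drug_id for d in self.drugs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate drug_id in panel")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.drugs)

    def targets_of(self, name_or_id: str) -> frozenset[str]:
        for d in self.drugs:
            if name_or_id in (d.drug_id, d.name):
                return d.targets
        raise KeyError(f"unknown drug {name_or_id!r}")


@dataclass(frozen=True)
class PathwayGraph:
    """Directed gene-gene graph used only by the topology prior."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))
        nodeset = set(self.nodes)
        for u, w in self.edges:
            if u == w:
                raise ValueError(f"self-loop {u!r} -> {w!r}")
            if u not in nodeset or w not in nodeset:
                raise ValueError(f"edge endpoint not in nodes: {(u, w)}")

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class ModelParameters:
    """All free parameters of the pathway-activity model.

    A_m[j], A_v[j]  activity contribution of gene j's mutation / copy-number
                    alteration, bounded to [-5, 5];
    rho[j, d]       drug influence coefficient: fraction of gene j's
                    alteration-induced activity reachable by drug d, in [0, 1];
    alpha[d]        drug effect: fractional inhibition applied to the activity
                    flowing through drug d's targets, in [0, 1];
    b[d]            per-drug intercept of the linear link dA = k*sens + b,
                    bounded to [-20, 20];
    k               fixed global scale of the link (not fitted; default 1).
    """

    genes: tuple[str, ...]
    drugs: tuple[str, ...]
    A_m: np.ndarray
    A_v: np.ndarray
    rho: np.ndarray
    alpha: np.ndarray
    b: np.ndarray
    k: float = 1.0

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.drugs = tuple(self.drugs)
        G, D = len(self.genes), len(self.drugs)
        self.A_m = np.asarray(self.A_m, dtype=float).reshape(G)
        self.A_v = np.asarray(self.A_v, dtype=float).reshape(G)
        self.rho = np.asarray(self.rho, dtype=float).reshape(G, D)
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(D)
        self.b = np.asarray(self.b, dtype=float).reshape(D)
        if not self.k > 0:
            raise ValueError("k must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def drug_index(self, drug: str) -> int:
        try:
            return self.drugs.index(drug)
        except ValueError:
            raise KeyError(f"unknown drug {drug!r}") from None

    def products(self) -> np.ndarray:
        """The (gene x drug) matrix of identifiable products rho * alpha."""
        return self.rho * self.alpha[None, :]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    delim = _infer_sep(path, sep)
    with open(path) as fh:  # pandas mangles duplicate headers; check raw
        header = fh.readline().rstrip("\r\n").split(delim)[1:]
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise ValueError(f"{path}: duplicate column identifier {dup!r}")
    df = pd.read_csv(path, sep=_infer_sep(path, sep), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample identifier {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate column identifier {dup!r}")
    return df


def read_alteration_tables(
    mutation_path: str | Path,
    cnv_path: str | Path,
    sep: str | None = None,
) -> AlterationProfile:
    """Read binary mutation and copy-number tables into one profile.

    Samples and genes are aligned to the intersection of the two files, in
    the order of the mutation file.  Entries must be coercible to {0, 1};
    the first offending cell is named in the error.
    """
    mdf = _read_table(mutation_path, sep)
    vdf = _read_table(cnv_path, sep)
    samples = [s for s in mdf.index if s in set(vdf.index)]
    genes = [g for g in mdf.columns if g in set(vdf.columns)]
    if not samples:
        raise ValueError("no samples shared between mutation and cnv tables")
    if not genes:
        raise ValueError("no genes shared between mutation and cnv tables")
    out = {}
    for name, df, path in (("mutation", mdf, mutation_path), ("copy-number", vdf, cnv_path)):
        sub = df.loc[samples, genes]
        vals = sub.to_numpy()
        numeric = sub.apply(lambda col: pd.to_numeric(col, errors="coerce"))
        arr = numeric.to_numpy(dtype=float)
        bad = ~np.isin(arr, (0.0, 1.0)) | ~np.isfinite(arr)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"{path}: non-binary entry {vals[r, c]!r} at "
                f"sample {samples[r]!r}, gene {genes[c]!r}"
            )
        out[name] = arr.astype(np.int8)
    return AlterationProfile(tuple(samples), tuple(genes), out["mutation"], out["copy-number"])


def read_response_table(path: str | Path, sep: str | None = None) -> ResponseTable:
    """Read a samples x drugs sensitivity table; blank/NA cells are masked."""
    df = _read_table(path, sep)
    sens = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    return ResponseTable.from_matrix(tuple(df.index), tuple(df.columns), sens)


def read_drug_panel(path: str | Path, sep: str | None = None) -> DrugPanel:
    """Read a drug panel file with columns drug_id, name, targets.

    Targets are semicolon-separated gene symbols; an empty cell means the
    drug has no (in-pathway) targets.
    """
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str)
    required = {"drug_id", "name", "targets"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: panel needs columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        raw = row["targets"]
        targets = frozenset(
            t.strip() for t in str(raw).split(";") if t.strip()
        ) if isinstance(raw, str) and raw.strip() else frozenset()
        records.append(DrugRecord(str(row["drug_id"]), str(row["name"]), targets))
    return DrugPanel(tuple(records))


def read_pathway_edges(path: str | Path) -> PathwayGraph:
    """Read a two-column directed edge list (whitespace/tab separated).

    Duplicate edges are collapsed; self-loops are dropped with a warning;
    a malformed line is rejected with its line number.
    """
    nodes: list[str] = []
    seen_nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    seen_edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            u, w = parts
            if u == w:
                warnings.warn(
                    f"{path}: dropping self-loop {u!r} at line {lineno}",
                    stacklevel=2,
                )
                if u not in seen_nodes:
                    seen_nodes.add(u)
                    nodes.append(u)
                continue
            for n in (u, w):
                if n not in seen_nodes:
                    seen_nodes.add(n)
                    nodes.append(n)
            if (u, w) not in seen_edges:
                seen_edges.add((u, w))
                edges.append((u, w))
    return PathwayGraph(tuple(nodes), tuple(edges))


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------


def write_alteration_tables(
    profile: AlterationProfile,
    mutation_path: str | Path,
    cnv_path: str | Path,
    sep: str | None = None,
) -> None:
    for mat, path in ((profile.m, mutation_path), (profile.v, cnv_path)):
        pd.DataFrame(mat, index=list(profile.samples), columns=list(profile.genes)).to_csv(
            path, sep=_infer_sep(path, sep)
        )


def write_response_table(
    responses: ResponseTable, path: str | Path, sep: str | None = None
) -> None:
    sens = np.where(responses.observed, responses.sens, np.nan)
    pd.DataFrame(sens, index=list(responses.samples), columns=list(responses.drugs)).to_csv(
        path, sep=_infer_sep(path, sep)
    )


def write_pathway_edges(graph: PathwayGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, w in graph.edges:
            fh.write(f"{u}\t{w}\n")
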