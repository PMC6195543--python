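"""Input/output: binary mutation matrices, prior interaction networks and
clinical tables.

The central container is :class:`MutationMatrix`: an ``N x n`` binary matrix
``D`` with ``D[i, j] = 1`` iff sample ``i`` carries at least one non-silent
mutation in gene ``j``.  Samples are rows throughout the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MutationMatrix",
    "PriorNetwork",
    "ClinicalTable",
    "DEFAULT_NONSILENT_CLASSES",
    "read_mutation_table",
    "write_mutation_table",
    "binarize_maf",
    "read_prior_network",
    "write_prior_network",
    "read_clinical",
    "recode_stage",
    "STAGE_LEVELS",
]


class FormatError(ValueError):
    """Malformed input table."""


# Variant classes counted as non-silent when binarising a MAF-like table.
# Configurable: gene-level presence/absence of any protein-altering variant.
DEFAULT_NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "Splice_Site",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)

STAGE_LEVELS = ("I", "II", "III", "IV", "X")


@dataclass
class MutationMatrix:
    """Binary sample-by-gene mutation matrix with identifiers.

    Parameters
    ----------
    samples : list of str
        Unique sample identifiers (rows).
    genes : list of str
        Unique gene symbols (columns).
    D : ndarray of shape (N, n)
        Entries in {0, 1}; ``D[i, j] = 1`` iff sample ``i`` has at least one
        qualifying mutation in gene ``j``.  All-zero rows are legitimate:
        samples without any mutation in the gene panel are kept.
    group : optional per-sample categorical labels (e.g. cancer type).
    """

    samples: list[str]
    genes: list[str]
    D: np.ndarray
    group: list[str] | None = None

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D)
        if self.D.ndim != 2:
            raise FormatError("D must be two-dimensional")
        N, n = self.D.shape
        if N < 1 or n < 1:
            raise FormatError("matrix must have at least one sample and one gene")
        if len(self.samples) != N or len(self.genes) != n:
            raise FormatError("identifier lengths do not match matrix shape")
        if len(set(self.samples)) != N:
            raise FormatError("duplicate sample identifiers")
        if len(set(self.genes)) != n:
            raise FormatError("duplicate gene symbols")
        bad = ~np.isin(self.D, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary entry {self.D[i, j]!r} at sample "
                f"{self.samples[i]!r}, gene {self.genes[j]!r}"
            )
        self.D = self.D.astype(np.int8)
        if self.group is not None and len(self.group) != N:
            raise FormatError("group labels must match the number of samples")

    @property
    def N(self) -> int:
        return self.D.shape[0]

    @property
    def n(self) -> int:
        return self.D.shape[1]

    def gene_frequencies(self) -> np.ndarray:
        """Per-gene mutation frequency across samples."""
        return self.D.mean(axis=0)

    def subset_samples(self, mask: np.ndarray) -> "MutationMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return MutationMatrix(
            [self.samples[i] for i in idx],
            list(self.genes),
            self.D[idx],
            [self.group[i] for i in idx] if self.group is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.samples, columns=self.genes)


@dataclass
class PriorNetwork:
    """Undirected prior over gene pairs (a STRING-style interaction list)."""

    edges: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise FormatError(f"prior edge {set(e)} is not a pair")

    def __contains__(self, pair: Iterable[str]) -> bool:
        return frozenset(pair) in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def to_adjacency(self, genes: Sequence[str]) -> np.ndarray:
        """Boolean symmetric adjacency over the given gene order."""
        pos = {g: i for i, g in enumerate(genes)}
        A = np.zeros((len(genes), len(genes)), dtype=bool)
        for e in self.edges:
            a, b = tuple(e)
            if a in pos and b in pos:
                A[pos[a], pos[b]] = A[pos[b], pos[a]] = True
        return A


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates for survival analysis.

    ``stage`` holds one of the five retained levels I--IV and X, where X
    pools every unclassifiable raw label; ``event`` is 1 for an observed
    death and 0 for censoring.
    """

    frame: pd.DataFrame

    REQUIRED = ("sample", "age", "stage", "cancer_type", "time", "event")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        f = self.frame
        complete = f[list(self.REQUIRED)].notna().all(axis=1)
        self.frame = f.assign(complete=complete)
        ok = self.frame.loc[complete]
        if (ok["time"] < 0).any():
            raise FormatError("negative follow-up time")
        if not ok["event"].isin([0, 1]).all():
            raise FormatError("event indicator must be 0 or 1")
        bad_stage = ~ok["stage"].isin(STAGE_LEVELS)
        if bad_stage.any():
            raise FormatError(
                f"unrecoded stage labels present: {sorted(ok.loc[bad_stage, 'stage'].unique())}"
            )

    def complete_cases(self) -> pd.DataFrame:
        """Rows with all required fields present (incomplete rows are flagged,
        not dropped silently, so the removed count can be reported)."""
        return self.frame.loc[self.frame["complete"]].drop(columns="complete")

    @property
    def n_removed(self) -> int:
        return int((~self.frame["complete"]).sum())


def read_mutation_table(path, dialect: str = "infer") -> MutationMatrix:
    """Read a TSV/CSV mutation matrix: header row of gene symbols, first
    column of sample identifiers, body strictly in {0, 1}."""
    sep = {"tsv": "\t", "csv": ",", "infer": None}[dialect]
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    try:
        body = df.to_numpy()
        return MutationMatrix(
            [str(s) for s in df.index], [str(g) for g in df.columns], body
        )
    except FormatError:
        raise
    except (TypeError, ValueError) as exc:  # non-numeric junk
        raise FormatError(f"could not parse mutation matrix {path}: {exc}") from exc


def write_mutation_table(matrix: MutationMatrix, path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep)


def binarize_maf(
    records: pd.DataFrame,
    gene_universe: Sequence[str],
    nonsilent_classes: Iterable[str] = DEFAULT_NONSILENT_CLASSES,
    samples: Sequence[str] | None = None,
) -> MutationMatrix:
    """Collapse a MAF-like record table to a binary gene-level matrix.

    Parameters
    ----------
    records : DataFrame
        Needs columns ``Hugo_Symbol``, ``Tumor_Sample_Barcode`` and
        ``Variant_Classification``.
    gene_universe : the analysis gene list (columns of the result).
    nonsilent_classes : variant classes that count as non-silent.
    samples : optional explicit sample list; defaults to the samples seen in
        ``records``.  Samples with no qualifying record are kept as all-zero
        rows.
    """
    gene_universe = list(gene_universe)
    if not gene_universe:
        raise ValueError("gene_universe must not be empty")
    need = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    missing = need - set(records.columns)
    if missing:
        raise FormatError(f"MAF table missing columns: {sorted(missing)}")
    nonsilent = set(nonsilent_classes)
    if samples is None:
        samples = list(pd.unique(records["Tumor_Sample_Barcode"].astype(str)))
    samples = [str(s) for s in samples]
    srow = {s: i for i, s in enumerate(samples)}
    gcol = {g: j for j, g in enumerate(gene_universe)}
    D = np.zeros((len(samples), len(gene_universe)), dtype=np.int8)
    keep = records["Variant_Classification"].isin(nonsilent)
    for _, rec in records.loc[keep].iterrows():
        i = srow.get(str(rec["Tumor_Sample_Barcode"]))
        j = gcol.get(str(rec["Hugo_Symbol"]))
        if i is not None and j is not None:
            D[i, j] = 1
    return MutationMatrix(samples, gene_universe, D)


def read_prior_network(path, gene_universe: Sequence[str]) -> PriorNetwork:
    """Read a two-column gene-pair edge list (extra columns ignored),
    restricted to pairs with both endpoints in ``gene_universe``."""
    universe = set(gene_universe)
    edges: set[frozenset[str]] = set()
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError("prior network needs at least two columns")
    for a, b in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        if a == b:
            continue
        if a not in universe or b not in universe:
            logger.warning("prior edge (%s, %s) outside gene universe; dropped", a, b)
            continue
        edges.add(frozenset((a, b)))
    return PriorNetwork(edges)


def write_prior_network(network: PriorNetwork, path) -> None:
    with open(path, "w") as fh:
        for e in sorted(tuple(sorted(x)) for x in network.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")


_STAGE_MAP = {
    "STAGE I": "I",
    "STAGE II": "II",
    "STAGE III": "III",
    "STAGE IV": "IV",
    "I": "I",
    "II": "II",
    "III": "III",
    "IV": "IV",
    "STAGE X": "X",
    "X": "X",
    "[NOT APPLICABLE]": "X",
    "[NOT AVAILABLE]": "X",
    "[DISCREPANCY]": "X",
    "[UNKNOWN]": "X",
}


def recode_stage(raw_label) -> str:
    """Map a raw tumour-stage label to one of the five retained levels.

    Stages I--IV map to themselves and are never merged; every
    unclassifiable label ('[Not Available]', '[Discrepancy]', 'Stage X',
    ...) is pooled into the single level X.  Total: never raises.
    """
    label = str(raw_label).strip().upper()
    # sub-stage suffixes like 'Stage IIIA' collapse to the main stage
    for main in ("IV", "III", "II", "I"):
        for suffix in ("A", "B", "C"):
            if label == f"STAGE {main}{suffix}" or label == f"{main}{suffix}":
                return main
    if label in _STAGE_MAP:
        return _STAGE_MAP[label]
    warnings.warn(f"unrecognised stage label {raw_label!r}; recoded to X")
    return "X"


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV/CSV and recode the stage column.

    Expected columns (case-insensitive match on these names): sample, age,
    stage, cancer_type, time, event.  Rows with missing required fields are
    flagged for removal, not dropped.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df["stage"] = [
            recode_stage(s) if pd.notna(s) else s for s in df.get("stage", [])
        ]
    return ClinicalTable(df)
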