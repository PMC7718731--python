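"""Core domain types and file I/O.

Genotypes are additive minor-allele counts in {0, 1, 2} and are *not*
centered or scaled: the model's intercept absorbs the mean.  Phenotypes
are plain numeric trait tables.  A causal structure is a t x t matrix of
structural coefficients Lambda whose nonzero support must form a directed
acyclic graph (entry ``lam[k, l] != 0`` means trait ``l`` causally affects
trait ``k``).
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeData",
    "PhenotypeData",
    "CausalStructure",
    "PriorConfig",
    "ChainConfig",
    "load_genotypes",
    "save_genotypes_csv",
    "save_genotypes_plink",
    "load_phenotypes",
    "save_phenotypes",
    "load_structure",
    "save_structure",
    "filter_maf",
    "align_individuals",
    "default_priors",
]

_ID_COLUMN_NAMES = {"id", "iid", "individual_id", "sample", "sample_id"}


class GenotypeCodingError(ValueError):
    """Raised when a genotype entry is not in {0, 1, 2}."""


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype files (duplicate ids, shape mismatch)."""


@dataclass
class GenotypeData:
    """n x p marker covariate matrix with its marker map.

    Attributes
    ----------
    matrix
        float64 array of shape (n, p) with entries in {0, 1, 2}.
    marker_ids
        p unique marker names.
    chrom
        p chromosome labels.
    order
        p integer map positions; markers are stored sorted by
        (chrom, order).
    individual_ids
        n individual names.
    """

    matrix: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    order: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chrom = np.asarray(self.chrom)
        self.order = np.asarray(self.order, dtype=np.int64)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n, p = self.matrix.shape
        if len(self.marker_ids) != p or len(self.chrom) != p or len(self.order) != p:
            raise GenotypeFormatError("map arrays do not match marker dimension")
        if len(self.individual_ids) != n:
            raise GenotypeFormatError("individual ids do not match row dimension")
        if len(set(self.marker_ids)) != p:
            raise GenotypeFormatError("duplicate marker ids")
        bad = ~np.isin(self.matrix, (0.0, 1.0, 2.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeCodingError(
                f"genotype entry {self.matrix[i, j]!r} at individual {i}, "
                f"marker {self.marker_ids[j]!r} is not in {{0,1,2}}"
            )
        # enforce map order
        key = np.lexsort((self.order, self.chrom.astype(str)))
        if not np.array_equal(key, np.arange(p)):
            self.matrix = self.matrix[:, key]
            self.marker_ids = self.marker_ids[key]
            self.chrom = self.chrom[key]
            self.order = self.order[key]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency f of the counted allele, mean(column)/2."""
        return self.matrix.mean(axis=0) / 2.0

    def map_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_ids, "chrom": self.chrom, "pos": self.order}
        )


@dataclass
class PhenotypeData:
    """n x t trait table."""

    matrix: np.ndarray
    trait_names: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.trait_names = np.asarray(self.trait_names, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("phenotype matrix must be 2-D")
        if self.matrix.shape[1] != len(self.trait_names):
            raise ValueError("trait names do not match column dimension")
        if self.matrix.shape[0] != len(self.individual_ids):
            raise ValueError("individual ids do not match row dimension")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def t(self) -> int:
        return self.matrix.shape[1]


class NonRecursiveStructureError(ValueError):
    """Raised when the support of Lambda contains a directed cycle."""


@dataclass
class CausalStructure:
    """t x t structural coefficient matrix Lambda.

    ``lam[k, l]`` is the effect of a one-unit increase in trait ``l`` on
    trait ``k``.  The support graph (edge l -> k for each nonzero entry)
    must be acyclic, so Lambda is permutation-similar to a strictly lower
    triangular matrix and det(I - Lambda) = 1.
    """

    lam: np.ndarray
    trait_names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=np.float64)
        t = self.lam.shape[0]
        if self.lam.shape != (t, t):
            raise ValueError("Lambda must be square")
        if self.trait_names is None:
            self.trait_names = np.array([f"trait{k + 1}" for k in range(t)], dtype=object)
        else:
            self.trait_names = np.asarray(self.trait_names, dtype=object)
        if np.any(np.diag(self.lam) != 0):
            raise NonRecursiveStructureError("diagonal of Lambda must be zero")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise NonRecursiveStructureError(
                "support of Lambda contains a directed cycle; "
                "a recursive (acyclic) system is required"
            )

    @property
    def t(self) -> int:
        return self.lam.shape[0]

    def graph(self) -> nx.DiGraph:
        """Directed graph with edge l -> k for each nonzero lam[k, l]."""
        g = nx.DiGraph()
        g.add_nodes_from(range(self.t))
        for k, l in zip(*np.nonzero(self.lam)):
            g.add_edge(int(l), int(k))
        return g

    def support(self) -> list[tuple[int, int]]:
        """Nonzero positions (k, l), sorted; defines the order of lambda."""
        return sorted((int(k), int(l)) for k, l in zip(*np.nonzero(self.lam)))

    def lambda_star(self) -> np.ndarray:
        """I - Lambda; its determinant is 1 for any recursive system."""
        return np.eye(self.t) - self.lam

    def topological_order(self) -> list[int]:
        return list(nx.topological_sort(self.graph()))

    def ancestors(self, k: int) -> set[int]:
        """Traits with a directed causal path into trait k."""
        return set(nx.ancestors(self.graph(), k))


@dataclass
class PriorConfig:
    """Hyperparameters of the inverse-Wishart / normal priors.

    S_e, nu_e parameterise R ~ IW(S_e * nu_e, nu_e) in the full-R model;
    s_e_diag holds the per-trait scales of the diagonal-R structural model.
    S_beta, nu_beta parameterise the marker-effect covariance
    G ~ IW(S_beta * nu_beta, nu_beta).  lambda0 and tau2 are the prior
    mean and variance of every structural coefficient.
    """

    S_e: np.ndarray
    nu_e: float
    S_beta: np.ndarray
    nu_beta: float
    s_e_diag: np.ndarray | None = None
    lambda0: float = 0.0
    tau2: float = 1.0

    def __post_init__(self) -> None:
        self.S_e = np.atleast_2d(np.asarray(self.S_e, dtype=np.float64))
        self.S_beta = np.atleast_2d(np.asarray(self.S_beta, dtype=np.float64))
        t = self.S_e.shape[0]
        if self.s_e_diag is None:
            self.s_e_diag = np.diag(self.S_e).copy()
        else:
            self.s_e_diag = np.asarray(self.s_e_diag, dtype=np.float64)
        if self.nu_e <= t - 1 or self.nu_beta <= t - 1:
            raise ValueError("degrees of freedom must exceed t - 1")
        if self.tau2 <= 0:
            raise ValueError("tau2 must be positive")
        for name, s in (("S_e", self.S_e), ("S_beta", self.S_beta)):
            if not np.allclose(s, s.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.linalg.eigvalsh(s) <= 0):
                raise ValueError(f"{name} must be positive definite")


@dataclass
class ChainConfig:
    """MCMC chain settings."""

    n_iter: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    output_every: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def default_priors(
    y: PhenotypeData, g: GenotypeData, expected_inclusion: float = 0.5
) -> PriorConfig:
    """Weakly informative defaults derived from the data.

    nu_e = nu_beta = t + 2, so the prior mean of an IW(S*nu, nu) equals
    S*nu.  S_e is chosen so the prior mean of R is half the sample
    phenotypic covariance; S_beta so the implied prior mean of the total
    genetic covariance (sum_j 2 f_j (1-f_j) times the expected inclusion
    probability times the per-effect covariance) is the other half.
    """
    t = y.t
    nu = float(t + 2)
    vy = np.atleast_2d(np.cov(y.matrix, rowvar=False))
    # keep the scale PD even for degenerate inputs
    vy = vy + 1e-8 * np.eye(t)
    f = g.allele_freq()
    msum = float(np.sum(2.0 * f * (1.0 - f)))
    msum = max(msum, 1e-8)
    mean_r = 0.5 * vy
    mean_g = 0.5 * vy / (msum * expected_inclusion)
    return PriorConfig(S_e=mean_r / nu, nu_e=nu, S_beta=mean_g / nu, nu_beta=nu)


# ---------------------------------------------------------------------------
# CSV I/O


def _split_ids(df: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    first = df.columns[0]
    if str(first).lower() in _ID_COLUMN_NAMES or df[first].dtype == object:
        ids = df[first].astype(str).to_numpy(dtype=object)
        return ids, df.drop(columns=[first])
    ids = np.array([f"ind{i}" for i in range(len(df))], dtype=object)
    return ids, df


def load_genotypes(
    path: str | Path,
    format: str = "csv",
    map_path: str | Path | None = None,
    missing: str = "error",
) -> GenotypeData:
    """Load a genotype matrix from CSV or a PLINK .bed/.bim/.fam triple.

    Parameters
    ----------
    path
        CSV file, or the PLINK prefix / .bed path.
    map_path
        Optional marker map CSV with columns marker_id, chrom, pos
        (CSV format only; PLINK carries its own map).
    missing
        "error" (default) rejects missing genotypes; "mode" fills each
        missing call with the column mode.
    """
    if format == "csv":
        df = pd.read_csv(path)
        ids, geno = _split_ids(df)
        marker_ids = np.asarray(geno.columns, dtype=object)
        mat = geno.to_numpy(dtype=np.float64)
        mat = _handle_missing(mat, marker_ids, missing)
        if map_path is not None:
            m = pd.read_csv(map_path)
            m = m.set_index("marker_id").loc[marker_ids]
            chrom = m["chrom"].to_numpy()
            order = m["pos"].to_numpy()
        else:
            chrom = np.ones(len(marker_ids), dtype=np.int64)
            order = np.arange(len(marker_ids))
        return GenotypeData(mat, marker_ids, chrom, order, ids)
    if format == "plink":
        return _read_plink(Path(path), missing=missing)
    raise ValueError(f"unknown genotype format {format!r}")


def _handle_missing(mat: np.ndarray, marker_ids: np.ndarray, policy: str) -> np.ndarray:
    miss = np.isnan(mat)
    if not miss.any():
        return mat
    if policy == "error":
        j = int(np.argwhere(miss.any(axis=0)).ravel()[0])
        raise GenotypeFormatError(
            f"missing genotype in marker {marker_ids[j]!r}; "
            "pass missing='mode' to impute with the column mode"
        )
    if policy != "mode":
        raise ValueError(f"unknown missing policy {policy!r}")
    for j in np.argwhere(miss.any(axis=0)).ravel():
        col = mat[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise GenotypeFormatError(f"marker {marker_ids[j]!r} entirely missing")
        vals, counts = np.unique(obs, return_counts=True)
        col[np.isnan(col)] = vals[np.argmax(counts)]
    return mat


def save_genotypes_csv(g: GenotypeData, path: str | Path, map_path: str | Path | None = None) -> None:
    df = pd.DataFrame(g.matrix.astype(np.int64), columns=g.marker_ids)
    df.insert(0, "id", g.individual_ids)
    df.to_csv(path, index=False)
    if map_path is not None:
        g.map_frame().to_csv(map_path, index=False)


def load_phenotypes(path: str | Path, drop_missing: bool = True) -> PhenotypeData:
    df = pd.read_csv(path)
    ids, ph = _split_ids(df)
    mat = ph.to_numpy(dtype=np.float64)
    if drop_missing:
        keep = ~np.isnan(mat).any(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d individuals with missing phenotypes", dropped)
        mat, ids = mat[keep], ids[keep]
    return PhenotypeData(mat, np.asarray(ph.columns, dtype=object), ids)


def save_phenotypes(y: PhenotypeData, path: str | Path) -> None:
    df = pd.DataFrame(y.matrix, columns=y.trait_names)
    df.insert(0, "id", y.individual_ids)
    df.to_csv(path, index=False)


def load_structure(path: str | Path) -> CausalStructure:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError("structure matrix must be square")
    return CausalStructure(df.to_numpy(dtype=np.float64), np.asarray(df.columns, dtype=object))


def save_structure(s: CausalStructure, path: str | Path) -> None:
    pd.DataFrame(s.lam, index=s.trait_names, columns=s.trait_names).to_csv(path)


def filter_maf(g: GenotypeData, min_maf: float) -> GenotypeData:
    """Keep markers with minor allele frequency >= min_maf.

    MAF is min(f, 1 - f) with f = mean(column) / 2.  Idempotent.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    f = g.allele_freq()
    maf = np.minimum(f, 1.0 - f)
    keep = maf >= min_maf
    if not keep.any():
        raise ValueError("all markers filtered: no marker passes the MAF threshold")
    return GenotypeData(
        g.matrix[:, keep], g.marker_ids[keep], g.chrom[keep], g.order[keep], g.individual_ids
    )


def align_individuals(g: GenotypeData, y: PhenotypeData) -> tuple[GenotypeData, PhenotypeData]:
    """Subset both tables to the id intersection, in genotype order."""
    common = [i for i in g.individual_ids if i in set(y.individual_ids)]
    dropped = (g.n - len(common)) + (y.n - len(common))
    if dropped:
        logger.info("alignment dropped %d unmatched individual records", dropped)
    if not common:
        raise ValueError("no shared individuals between genotypes and phenotypes")
    gi = {v: i for i, v in enumerate(g.individual_ids)}
    yi = {v: i for i, v in enumerate(y.individual_ids)}
    gr = [gi[c] for c in common]
    yr = [yi[c] for c in common]
    g2 = GenotypeData(g.matrix[gr], g.marker_ids, g.chrom, g.order, np.asarray(common, dtype=object))
    y2 = PhenotypeData(y.matrix[yr], y.trait_names, np.asarray(common, dtype=object))
    return g2, y2


# ---------------------------------------------------------------------------
# PLINK binary triple (.bed/.bim/.fam), SNP-major additive coding.
# Two-bit codes per individual: 00 = hom A1 (count 2), 10 = het (1),
# 11 = hom A2 (0), 01 = missing.  A1 is the counted (minor) allele.

_BED_MAGIC = b"\x6c\x1b\x01"


def _bed_lut() -> np.ndarray:
    lut = np.empty((256, 4), dtype=np.float64)
    code = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}
    for byte in range(256):
        for k in range(4):
            lut[byte, k] = code[(byte >> (2 * k)) & 0b11]
    return lut


_LUT = _bed_lut()


def _read_plink(prefix: Path, missing: str = "error") -> GenotypeData:
    prefix = Path(str(prefix).removesuffix(".bed"))
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    ids = fam[1].astype(str).to_numpy(dtype=object)
    n, p = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeFormatError("not a SNP-major PLINK .bed file")
    stride = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != stride * p:
        raise GenotypeFormatError(".bed size does not match .bim/.fam dimensions")
    mat = _LUT[body.reshape(p, stride)].reshape(p, stride * 4)[:, :n].T.copy()
    marker_ids = bim["marker_id"].astype(str).to_numpy(dtype=object)
    mat = _handle_missing(mat, marker_ids, missing)
    return GenotypeData(mat, marker_ids, bim["chrom"].to_numpy(), bim["pos"].to_numpy(), ids)


def save_genotypes_plink(g: GenotypeData, prefix: str | Path) -> None:
    """Write a PLINK .bed/.bim/.fam triple (SNP-major, A1 = counted allele)."""
    prefix = Path(prefix)
    bim = pd.DataFrame(
        {
            "chrom": g.chrom,
            "marker_id": g.marker_ids,
            "cm": 0,
            "pos": g.order,
            "a1": "A",
            "a2": "B",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            0: g.individual_ids,
            1: g.individual_ids,
            2: 0,
            3: 0,
            4: 0,
            5: -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    n, p = g.n, g.p
    stride = (n + 3) // 4
    to_code = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = bytearray(stride)
        for j in range(p):
            for b in range(stride):
                buf[b] = 0
            col = g.matrix[:, j]
            for i in range(n):
                buf[i // 4] |= to_code[col[i]] << (2 * (i % 4))
            fh.write(bytes(buf))
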