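"""Region genotype data: containers, I/O, QC, imputation, position scaling.

A region is held as a :class:`GenotypeMatrix`: an ``n x p`` matrix of
minor-allele dosages (0, 1, 2, or missing) for ``n`` subjects at ``p``
biallelic variants with known physical positions, together with the
binary (or k-level) phenotype labels used for the association test.
Missing entries are represented by ``numpy.nan`` in a float matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_CODES = (0.0, 1.0, 2.0)


class GenotypeDataError(ValueError):
    """Raised for unusable genotype input (empty region, bad codes, ...)."""


@dataclass
class GenotypeMatrix:
    """Genotypes for one genomic region.

    Parameters
    ----------
    codes
        ``n x p`` float matrix with entries in {0, 1, 2} or ``nan`` (missing).
        Codes count copies of the coded (normally minor) allele.
    positions
        Physical coordinates (base pairs, 1-based, strictly increasing) of the
        ``p`` variants, or ``None`` when unknown.
    sample_ids
        ``n`` subject identifiers.
    groups
        ``n`` phenotype labels (e.g. ``"case"`` / ``"control"``), or ``None``
        before phenotypes are attached.
    scaled_positions
        Variant positions mapped to [0, 1]; filled in by
        :func:`scale_positions`.
    region_id
        Free-text region name.
    """

    codes: np.ndarray
    positions: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)
    groups: np.ndarray | None = None
    scaled_positions: np.ndarray | None = None
    region_id: str = "region"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise GenotypeDataError("codes must be a 2-D (subjects x variants) matrix")
        vals = self.codes[~np.isnan(self.codes)]
        if vals.size and not np.isin(vals, _VALID_CODES).all():
            raise GenotypeDataError("genotype codes must be 0, 1, 2 or missing")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(self.codes.shape[0])]
        if len(self.sample_ids) != self.codes.shape[0]:
            raise GenotypeDataError("sample_ids length does not match codes")
        if self.positions is not None:
            self.positions = np.asarray(self.positions)
            if self.positions.shape != (self.codes.shape[1],):
                raise GenotypeDataError("positions length does not match codes")
            if self.positions.size > 1 and not (np.diff(self.positions) > 0).all():
                raise GenotypeDataError("positions must be strictly increasing")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape != (self.codes.shape[0],):
                raise GenotypeDataError("groups length does not match codes")

    # -- basic queries -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.codes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.codes.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.codes).any())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            codes=self.codes.copy(),
            positions=None if self.positions is None else self.positions.copy(),
            sample_ids=list(self.sample_ids),
            groups=None if self.groups is None else self.groups.copy(),
            scaled_positions=(
                None if self.scaled_positions is None else self.scaled_positions.copy()
            ),
            region_id=self.region_id,
        )

    # -- I/O -----------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write codes as TSV: header = positions, first column = sample ID."""
        pos = (
            self.positions
            if self.positions is not None
            else np.arange(1, self.n_variants + 1)
        )
        df = pd.DataFrame(self.codes, index=self.sample_ids, columns=pos)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", na_rep="NA")

    def phenotype_to_tsv(self, path: str | Path) -> None:
        if self.groups is None:
            raise GenotypeDataError("no phenotype labels to write")
        pd.DataFrame({"sample_id": self.sample_ids, "label": self.groups}).to_csv(
            path, sep="\t", index=False, header=False
        )


def _read_phenotype(phenotype: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(phenotype, Mapping):
        return dict(phenotype)
    df = pd.read_csv(phenotype, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise GenotypeDataError("phenotype file needs two columns: sample ID, label")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def recode_to_minor(G: GenotypeMatrix) -> GenotypeMatrix:
    """Flip variant coding so the coded allele is the sample minor allele.

    The minor allele is decided by allele frequency across all retained
    subjects; at an exact 0.5 frequency the current coded allele is kept.
    """
    out = G.copy()
    with np.errstate(invalid="ignore"):
        af = np.nanmean(out.codes, axis=0) / 2.0
    flip = af > 0.5
    out.codes[:, flip] = 2.0 - out.codes[:, flip]
    return out


def read_genotypes(
    source: str | Path,
    phenotype: str | Path | Mapping[str, str] | None = None,
    region: tuple[str, int, int] | str | None = None,
    region_id: str | None = None,
) -> GenotypeMatrix:
    """Read a region genotype matrix from a VCF (``.vcf``/``.vcf.gz``) or TSV.

    TSV layout: first row holds variant positions, first column sample IDs.
    VCF input keeps biallelic SNPs only (multi-allelic records are skipped
    with a warning) and recodes dosages so the coded allele is the minor
    allele in the retained sample. ``region`` is a half-open window
    ``(chrom, start, end)`` or a ``"chrom:start-end"`` string.

    When ``phenotype`` is given, samples without a label are dropped (with a
    warning) and the remaining labels are attached as ``groups``.
    """
    source = Path(source)
    if not source.exists():
        raise GenotypeDataError(f"cannot read genotype source: {source}")
    if source.suffix in (".vcf", ".gz", ".bcf"):
        G = _read_vcf(source, region)
    else:
        G = _read_tsv(source)
    if region_id is not None:
        G.region_id = region_id

    if phenotype is not None:
        labels = _read_phenotype(phenotype)
        keep = [i for i, s in enumerate(G.sample_ids) if s in labels]
        if not keep:
            raise GenotypeDataError("no sample has a phenotype label")
        if len(keep) < G.n_subjects:
            logger.warning(
                "dropping %d samples without phenotype labels",
                G.n_subjects - len(keep),
            )
            G = GenotypeMatrix(
                codes=G.codes[keep],
                positions=G.positions,
                sample_ids=[G.sample_ids[i] for i in keep],
                region_id=G.region_id,
            )
        G.groups = np.array([labels[s] for s in G.sample_ids])
        G = recode_to_minor(G)
    return G


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ".", ""])
    if df.shape[1] == 0:
        raise GenotypeDataError("zero variants in TSV")
    positions = np.array([int(float(c)) for c in df.columns])
    return GenotypeMatrix(
        codes=df.to_numpy(dtype=float),
        positions=positions,
        sample_ids=[str(s) for s in df.index],
        region_id=path.stem,
    )


def _parse_region(region) -> tuple[str, int, int] | None:
    if region is None:
        return None
    if isinstance(region, str):
        chrom, _, span = region.partition(":")
        if not span:
            return (chrom, 0, np.iinfo(np.int64).max)
        start, _, end = span.partition("-")
        return (chrom, int(start), int(end))
    return region


def _read_vcf(path: Path, region) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise GenotypeDataError("cyvcf2 is required for VCF input") from exc

    win = _parse_region(region)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    positions: list[int] = []
    ids: list[str] = []
    for v in vcf:
        if win is not None and (v.CHROM != win[0] or not win[1] <= v.POS < win[2]):
            continue
        if len(v.ALT) != 1:
            logger.warning("skipping multi-allelic site %s:%d", v.CHROM, v.POS)
            continue
        gts = np.array([g[:2] for g in v.genotypes], dtype=float)
        dose = gts.sum(axis=1)
        dose[(gts < 0).any(axis=1)] = np.nan
        rows.append(dose)
        positions.append(v.POS)
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
    if not rows:
        raise GenotypeDataError("zero variants in region")
    order = sorted(range(len(positions)), key=lambda i: (positions[i], ids[i]))
    codes = np.column_stack([rows[i] for i in order])
    G = GenotypeMatrix(
        codes=codes,
        positions=np.array([positions[i] for i in order]),
        sample_ids=samples,
        region_id=path.stem,
    )
    return recode_to_minor(G)


# -- quality control -------------------------------------------------------


def apply_qc(
    G: GenotypeMatrix,
    max_subject_missing: float = 0.30,
    min_variant_callrate: float = 0.70,
    drop_monomorphic: bool = True,
) -> GenotypeMatrix:
    """QC-filter a region: subjects, then variants, then monomorphic columns.

    Subjects with a missing-genotype fraction above ``max_subject_missing``
    are removed first; then variants observed in fewer than
    ``min_variant_callrate`` of the remaining subjects; finally variants
    whose (non-missing) codes are constant across all remaining subjects.
    Row/column order is preserved. Idempotent.
    """
    if G.n_subjects == 0 or G.n_variants == 0:
        raise GenotypeDataError("empty genotype matrix")
    miss = np.isnan(G.codes)
    keep_s = miss.mean(axis=1) <= max_subject_missing
    if not keep_s.any():
        raise GenotypeDataError("empty after QC: all subjects removed")
    codes = G.codes[keep_s]
    callrate = 1.0 - np.isnan(codes).mean(axis=0)
    keep_v = callrate >= min_variant_callrate
    codes = codes[:, keep_v]
    if drop_monomorphic and codes.size:
        with np.errstate(invalid="ignore"):
            poly = np.nanmax(codes, axis=0) != np.nanmin(codes, axis=0)
        codes = codes[:, poly]
        keep_v[keep_v] = poly
    if codes.shape[1] == 0:
        raise GenotypeDataError("empty after QC: all variants removed")
    logger.info(
        "QC %s: removed %d/%d subjects, %d/%d variants",
        G.region_id,
        int((~keep_s).sum()),
        G.n_subjects,
        int((~keep_v).sum()),
        G.n_variants,
    )
    return GenotypeMatrix(
        codes=codes,
        positions=None if G.positions is None else G.positions[keep_v],
        sample_ids=[s for s, k in zip(G.sample_ids, keep_s) if k],
        groups=None if G.groups is None else G.groups[keep_s],
        scaled_positions=None,
        region_id=G.region_id,
    )


def impute_missing(
    G: GenotypeMatrix, method: str = "mode", seed: int | None = None
) -> GenotypeMatrix:
    """Single imputation of missing codes, per variant.

    ``mode`` fills each variant's missing entries with its most frequent
    observed code (ties go to the smaller code); ``empirical-draw`` samples
    from the variant's observed code frequencies using ``seed``. Identity on
    complete matrices.
    """
    if method not in ("mode", "empirical-draw"):
        raise ValueError(f"unknown imputation method: {method}")
    out = G.copy()
    miss = np.isnan(out.codes)
    if not miss.any():
        return out
    if np.all(miss, axis=0).any():
        raise GenotypeDataError("cannot impute a variant that is entirely missing")
    rng = np.random.default_rng(seed)
    for j in np.flatnonzero(miss.any(axis=0)):
        col = out.codes[:, j]
        obs = col[~np.isnan(col)]
        counts = np.array([(obs == c).sum() for c in (0.0, 1.0, 2.0)])
        if method == "mode":
            fill = float(np.argmax(counts))  # argmax ties -> smaller code
            col[np.isnan(col)] = fill
        else:
            freqs = counts / counts.sum()
            col[np.isnan(col)] = rng.choice([0.0, 1.0, 2.0], np.isnan(col).sum(), p=freqs)
    logger.info("imputed %d missing entries (%s, single imputation)", int(miss.sum()), method)
    return out


def scale_positions(G: GenotypeMatrix) -> GenotypeMatrix:
    """Map variant positions onto [0, 1].

    With known physical positions the map is affine,
    ``s_j = (pos_j - pos_1) / (pos_p - pos_1)``; without positions the
    variants are assumed equally spaced, ``s_j = (j - 1)/(p - 1)``.
    """
    p = G.n_variants
    if p < 2:
        raise GenotypeDataError("need at least 2 variants to scale positions")
    if G.positions is not None:
        pos = np.asarray(G.positions, dtype=float)
        if np.unique(pos).size != pos.size:
            raise GenotypeDataError("duplicate physical positions")
        scaled = (pos - pos[0]) / (pos[-1] - pos[0])
    else:
        scaled = np.arange(p) / (p - 1)
    out = G.copy()
    out.scaled_positions = scaled
    return out
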