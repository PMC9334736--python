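"""Multi-organ circadian expression atlas: data model, I/O, and filtering.

The central container is :class:`ExpressionAtlas`, a dense gene x organ x
time-point array of non-negative, FPKM-like expression values sampled at
equally spaced Zeitgeber times (ZT) within one circadian cycle.  One animal
(one value) per organ per time point is assumed, mirroring primate and mouse
circadian atlases where organs play the role of replicates at each ZT.

On-disk format is a wide TSV: one gene-identifier column plus one column per
(organ, ZT) sample, named ``ORGAN_ZT06`` by default (configurable through a
small layout descriptor).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AtlasFormatError",
    "ColumnLayout",
    "ExpressionAtlas",
    "read_atlas",
    "write_atlas",
    "filter_expressed",
    "standardize_per_organ",
    "assign_day_night",
]


class AtlasFormatError(ValueError):
    """Raised when an on-disk atlas violates the format contract."""


@dataclass(frozen=True)
class ColumnLayout:
    """Maps wide-TSV column names to (organ, ZT) pairs.

    Default convention: ``<ORGAN><sep>ZT<hh>``, e.g. ``LIVER_ZT06``.
    """

    gene_column: str = "gene"
    sep: str = "_ZT"

    def parse(self, column: str) -> tuple[str, float] | None:
        m = re.fullmatch(rf"(.+){re.escape(self.sep)}(\d+(?:\.\d+)?)", column)
        if m is None:
            return None
        return m.group(1), float(m.group(2))

    def format(self, organ: str, zt: float) -> str:
        if float(zt).is_integer():
            return f"{organ}{self.sep}{int(zt):02d}"
        return f"{organ}{self.sep}{zt}"


@dataclass
class ExpressionAtlas:
    """Gene x organ x time expression cube with circadian time metadata.

    Parameters
    ----------
    gene_ids, organ_ids
        Ordered unique identifiers.
    zt_times
        Strictly increasing ZT hours, all in ``[0, period_hours)``, equally
        spaced.
    values
        Array of shape ``(n_genes, n_organs, n_times)``; non-negative unless
        the atlas has been standardized (``standardized=True``).
    """

    gene_ids: list[str]
    organ_ids: list[str]
    zt_times: np.ndarray
    values: np.ndarray
    period_hours: float = 24.0
    standardized: bool = False
    flagged_constant: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.zt_times = np.asarray(self.zt_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n_g, n_o, n_t = len(self.gene_ids), len(self.organ_ids), len(self.zt_times)
        if self.values.shape != (n_g, n_o, n_t):
            raise AtlasFormatError(
                f"values shape {self.values.shape} != ({n_g}, {n_o}, {n_t})"
            )
        if len(set(self.gene_ids)) != n_g:
            raise AtlasFormatError("duplicate gene identifiers")
        if len(set(self.organ_ids)) != n_o:
            raise AtlasFormatError("duplicate organ identifiers")
        if n_t >= 2:
            diffs = np.diff(self.zt_times)
            if np.any(diffs <= 0):
                raise AtlasFormatError("zt_times must be strictly increasing")
            if not np.allclose(diffs, diffs[0]):
                raise AtlasFormatError("zt_times must be equally spaced")
        if np.any(self.zt_times < 0) or np.any(self.zt_times >= self.period_hours):
            raise AtlasFormatError("zt_times must lie in [0, period_hours)")
        if np.any(np.isnan(self.values)):
            raise AtlasFormatError("missing values are not allowed in the core pipeline")
        if not self.standardized and np.any(self.values < 0):
            g, o, t = map(int, np.argwhere(self.values < 0)[0])
            raise AtlasFormatError(
                f"negative expression at gene={self.gene_ids[g]}, "
                f"organ={self.organ_ids[o]}, ZT={self.zt_times[t]:g}"
            )

    # -- basic introspection -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_organs(self) -> int:
        return len(self.organ_ids)

    @property
    def n_times(self) -> int:
        return len(self.zt_times)

    @property
    def sampling_interval(self) -> float:
        if self.n_times < 2:
            raise ValueError("need >= 2 time points for a sampling interval")
        return float(self.zt_times[1] - self.zt_times[0])

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def subset_genes(self, genes: list[str]) -> "ExpressionAtlas":
        idx = [self.gene_index(g) for g in genes]
        return replace(self, gene_ids=list(genes), values=self.values[idx])

    def drop_organ(self, organ: str) -> "ExpressionAtlas":
        keep = [i for i, o in enumerate(self.organ_ids) if o != organ]
        if len(keep) == len(self.organ_ids):
            raise KeyError(f"unknown organ {organ!r}")
        return replace(
            self,
            organ_ids=[self.organ_ids[i] for i in keep],
            values=self.values[:, keep, :],
        )

    def to_frame(self, layout: ColumnLayout | None = None) -> pd.DataFrame:
        layout = layout or ColumnLayout()
        cols = {}
        for o_i, organ in enumerate(self.organ_ids):
            for t_i, zt in enumerate(self.zt_times):
                cols[layout.format(organ, zt)] = self.values[:, o_i, t_i]
        frame = pd.DataFrame(cols, index=pd.Index(self.gene_ids, name=layout.gene_column))
        return frame


def read_atlas(
    path,
    layout: ColumnLayout | None = None,
    period_hours: float = 24.0,
) -> ExpressionAtlas:
    """Read a wide TSV expression matrix into an :class:`ExpressionAtlas`.

    Columns that do not match the layout convention are rejected with an
    error naming them; duplicate gene identifiers and negative or
    non-numeric values are format errors.
    """
    layout = layout or ColumnLayout()
    frame = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    if layout.gene_column not in frame.columns:
        raise AtlasFormatError(
            f"missing gene column {layout.gene_column!r} in {path}"
        )
    parsed = {}
    bad = []
    for col in frame.columns:
        if col == layout.gene_column:
            continue
        hit = layout.parse(col)
        if hit is None:
            bad.append(col)
        else:
            parsed[col] = hit
    if bad:
        raise AtlasFormatError(f"unparseable sample columns: {bad}")
    if not parsed:
        raise AtlasFormatError("no sample columns found")

    genes = frame[layout.gene_column].tolist()
    if len(set(genes)) != len(genes):
        dupes = frame[layout.gene_column][frame[layout.gene_column].duplicated()]
        raise AtlasFormatError(f"duplicate gene identifiers: {sorted(set(dupes))[:5]}")

    organs = list(dict.fromkeys(org for org, _ in parsed.values()))
    zts = sorted({zt for _, zt in parsed.values()})
    values = np.full((len(genes), len(organs), len(zts)), np.nan)
    o_idx = {o: i for i, o in enumerate(organs)}
    t_idx = {z: i for i, z in enumerate(zts)}
    for col, (organ, zt) in parsed.items():
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise AtlasFormatError(
                f"non-numeric expression at gene={genes[row]}, column={col}"
            )
        values[:, o_idx[organ], t_idx[zt]] = numeric.to_numpy()
    if np.any(np.isnan(values)):
        raise AtlasFormatError("ragged layout: some (organ, ZT) cells absent")
    neg = np.argwhere(values < 0)
    if neg.size:
        g, o, t = map(int, neg[0])
        raise AtlasFormatError(
            f"negative expression at gene={genes[g]}, organ={organs[o]}, ZT={zts[t]:g}"
        )
    return ExpressionAtlas(
        gene_ids=genes,
        organ_ids=organs,
        zt_times=np.array(zts, dtype=float),
        values=values,
        period_hours=period_hours,
    )


def write_atlas(atlas: ExpressionAtlas, path, layout: ColumnLayout | None = None) -> None:
    """Write an atlas to wide TSV (round-trips with :func:`read_atlas`)."""
    frame = atlas.to_frame(layout)
    frame.to_csv(path, sep="\t", float_format="%.10g")


def filter_expressed(
    atlas: ExpressionAtlas,
    organ_rule: str = "all",
    threshold: float = 0.0,
) -> tuple[ExpressionAtlas, pd.DataFrame]:
    """Keep genes expressed above ``threshold`` at >= half of the time points.

    A gene counts as expressed *within one organ* if its value is strictly
    greater than ``threshold`` at at least half of the ZT samples of that
    organ.  ``organ_rule`` decides how per-organ verdicts combine:
    ``"all"`` (default) requires the gene to pass in every organ so that the
    stacked multi-organ series has no organ-specific gaps; ``"any"`` keeps
    genes expressed in at least one organ.

    Returns the filtered atlas and a per-gene audit table with the number of
    passing organs and the retention verdict.
    """
    if organ_rule not in ("all", "any"):
        raise ValueError(f"organ_rule must be 'all' or 'any', got {organ_rule!r}")
    n_t = atlas.n_times
    need = (n_t + 1) // 2  # at least half of all the time points
    per_organ_pass = (atlas.values > threshold).sum(axis=2) >= need  # genes x organs
    n_pass = per_organ_pass.sum(axis=1)
    if organ_rule == "all":
        keep = n_pass == atlas.n_organs
    else:
        keep = n_pass >= 1
    audit = pd.DataFrame(
        {
            "gene": atlas.gene_ids,
            "organs_expressed": n_pass,
            "retained": keep,
        }
    )
    if not keep.any():
        raise ValueError("no genes pass the expression filter")
    kept_genes = [g for g, k in zip(atlas.gene_ids, keep) if k]
    filtered = replace(atlas, gene_ids=kept_genes, values=atlas.values[keep])
    return filtered, audit


def standardize_per_organ(atlas: ExpressionAtlas) -> ExpressionAtlas:
    """Location/scale standardize each gene x organ time series.

    Each series becomes mean 0, population sd 1; constant series are set to
    all-zero and recorded in ``flagged_constant``.  Idempotent, and
    rank-preserving within every (organ, ZT) slice up to an affine map, so
    Spearman correlations between genes are untouched.
    """
    vals = atlas.values
    mean = vals.mean(axis=2, keepdims=True)
    sd = vals.std(axis=2, keepdims=True)
    degenerate = sd[:, :, 0] == 0
    out = np.zeros_like(vals)
    np.divide(vals - mean, sd, out=out, where=sd > 0)
    flagged = [
        (atlas.gene_ids[g], atlas.organ_ids[o]) for g, o in np.argwhere(degenerate)
    ]
    return replace(atlas, values=out, standardized=True, flagged_constant=flagged)


def assign_day_night(
    zt: float,
    day_start: float = 0.0,
    day_end: float = 12.0,
    period_hours: float = 24.0,
) -> str:
    """Classify a ZT hour as ``"day"`` or ``"night"``.

    Day is the half-open window ``[day_start, day_end)``; with the default
    12:12 schedule ZT06 (noon) is day and ZT12 onwards (through ZT18,
    midnight) is night.
    """
    if not 0 <= zt < period_hours:
        raise ValueError(f"ZT {zt} outside [0, {period_hours})")
    return "day" if day_start <= zt < day_end else "night"
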