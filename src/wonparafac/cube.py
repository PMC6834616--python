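"""Build the non-negative multi-omics data cube and its weight tensor.

Heterogeneous per-data-type matrices (continuous expression, copy number,
binary mutation calls) are standardized, made non-negative by sign
splitting, aligned on shared gene/sample identifiers and stacked into a
genes x samples x layers array.  The accompanying weight tensor down-weights
high-variance layers (weight 1/||X_d||_F^2 per layer) so that no single
data type dominates the joint factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXPRESSION = "expression"
COPY_NUMBER = "copy_number"
MUTATION = "mutation"
LAYER_KINDS = (EXPRESSION, COPY_NUMBER, MUTATION)


class AlignmentError(ValueError):
    """Gene/sample identifier axes cannot be reconciled."""


@dataclass
class OmicsLayer:
    """One genes x samples matrix of a single data type."""

    name: str
    kind: str
    values: np.ndarray
    gene_ids: list
    sample_ids: list
    zero_variance_genes: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match identifier lengths")
        for axis_name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {axis_name} identifiers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str, kind: str) -> "OmicsLayer":
        return cls(name=name, kind=kind, values=df.to_numpy(dtype=float),
                   gene_ids=list(df.index), sample_ids=list(df.columns))


@dataclass
class DataCube:
    """Aligned non-negative genes x samples x layers array."""

    values: np.ndarray
    gene_ids: list
    sample_ids: list
    layer_names: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.layer_names = list(self.layer_names)
        expected = (len(self.gene_ids), len(self.sample_ids), len(self.layer_names))
        if self.values.shape != expected:
            raise ValueError(f"cube shape {self.values.shape} != ids {expected}")
        if np.any(self.values < 0):
            raise ValueError("cube entries must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def layer(self, name: str) -> np.ndarray:
        return self.values[:, :, self.layer_names.index(name)]


@dataclass
class WeightTensor:
    """Per-entry loss weights, constant within each layer slab."""

    values: np.ndarray
    layer_weights: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.layer_weights = np.asarray(self.layer_weights, dtype=float)
        if np.any(self.values < 0) or np.any(self.layer_weights < 0):
            raise ValueError("weights must be non-negative")


def standardize_expression(
    layer: OmicsLayer,
    ref_means: np.ndarray | None = None,
    ref_sds: np.ndarray | None = None,
    sd: str = "population",
) -> OmicsLayer:
    """Mean-center and scale each gene row by its standard deviation.

    When reference statistics are absent they are computed per gene across
    the layer's own samples (an independent cohort passes its own, see the
    projection pipeline).  Zero-variance genes come back as all-zero rows,
    listed in ``zero_variance_genes``.
    """
    if layer.kind != EXPRESSION:
        raise ValueError("standardize_expression requires an expression layer")
    if sd not in ("population", "sample"):
        raise ValueError("sd must be 'population' or 'sample'")
    X = layer.values
    if (ref_means is None) != (ref_sds is None):
        raise AlignmentError("ref_means and ref_sds must be given together")
    if ref_means is None:
        means = X.mean(axis=1)
        sds = X.std(axis=1, ddof=0 if sd == "population" else 1)
    else:
        means = np.asarray(ref_means, dtype=float)
        sds = np.asarray(ref_sds, dtype=float)
        if means.shape != (X.shape[0],) or sds.shape != (X.shape[0],):
            raise AlignmentError("reference statistics do not match the gene axis")
    zero = sds <= 0
    safe = np.where(zero, 1.0, sds)
    Z = (X - means[:, None]) / safe[:, None]
    Z[zero, :] = 0.0
    return OmicsLayer(
        name=layer.name, kind=layer.kind, values=Z,
        gene_ids=layer.gene_ids, sample_ids=layer.sample_ids,
        zero_variance_genes=[g for g, z in zip(layer.gene_ids, zero) if z],
    )


def ternarize_copy_number(
    layer: OmicsLayer, gain_threshold: float = 5.0, loss_threshold: float = 1.0
) -> OmicsLayer:
    """Reduce copy number to gain/neutral/loss states {1, 0, -1}.

    Gain is strict (> gain_threshold), loss non-strict (<= loss_threshold).
    """
    if layer.kind != COPY_NUMBER:
        raise ValueError("ternarize_copy_number requires a copy_number layer")
    X = layer.values
    if np.any(X < 0):
        raise ValueError("raw copy number must be non-negative")
    T = np.zeros_like(X)
    T[X > gain_threshold] = 1.0
    T[X <= loss_threshold] = -1.0
    return OmicsLayer(name=layer.name, kind=layer.kind, values=T,
                      gene_ids=layer.gene_ids, sample_ids=layer.sample_ids)


def binarize_mutation(layer: OmicsLayer) -> OmicsLayer:
    """Convert any nonzero mutation indicator to 1."""
    if layer.kind != MUTATION:
        raise ValueError("binarize_mutation requires a mutation layer")
    return OmicsLayer(name=layer.name, kind=layer.kind,
                      values=(layer.values != 0).astype(float),
                      gene_ids=layer.gene_ids, sample_ids=layer.sample_ids)


def sign_split(layer: OmicsLayer) -> tuple[OmicsLayer, OmicsLayer]:
    """Split a mixed-sign layer into non-negative (+) and (-) parts.

    plus = max(x, 0), minus = max(-x, 0); plus - minus reconstructs the
    input exactly.
    """
    if layer.kind == MUTATION:
        raise ValueError("mutation layers are binary; sign_split does not apply")
    X = layer.values
    mk = dict(kind=layer.kind, gene_ids=layer.gene_ids, sample_ids=layer.sample_ids)
    plus = OmicsLayer(name=f"{layer.name}(+)", values=np.maximum(X, 0.0), **mk)
    minus = OmicsLayer(name=f"{layer.name}(-)", values=np.maximum(-X, 0.0), **mk)
    return plus, minus


def build_cube(
    layers: list[OmicsLayer],
    gene_subset: list | None = None,
    pad_missing_genes: bool = False,
) -> tuple[DataCube, dict]:
    """Stack prepared non-negative layers into an aligned cube.

    Genes and samples are restricted to the intersection across layers
    (and to ``gene_subset`` when given), kept in the first layer's order.
    With ``pad_missing_genes`` a gene present in at least one layer is kept
    and zero-filled (and flagged) in layers that lack it — useful when a
    panel gene was not assayed in one data type.  Returns the cube and an
    alignment report of dropped/padded identifiers.
    """
    if not layers:
        raise ValueError("no layers given")
    genes = list(layers[0].gene_ids)
    samples = list(layers[0].sample_ids)
    for lay in layers[1:]:
        gset, sset = set(lay.gene_ids), set(lay.sample_ids)
        if pad_missing_genes:
            genes += [g for g in lay.gene_ids if g not in set(genes)]
        else:
            genes = [g for g in genes if g in gset]
        samples = [s for s in samples if s in sset]
    if gene_subset is not None:
        keep = set(gene_subset)
        genes = [g for g in genes if g in keep]
    if not genes or not samples:
        raise AlignmentError("empty gene or sample intersection across layers")

    padded: dict[str, list] = {}
    slabs = []
    for lay in layers:
        df = lay.to_frame()
        if pad_missing_genes:
            missing = [g for g in genes if g not in set(lay.gene_ids)]
            if missing:
                padded[lay.name] = missing
            df = df.reindex(index=genes, fill_value=0.0)
        df = df.loc[genes, samples]
        vals = df.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError(f"layer {lay.name!r} has negative entries; "
                             "sign-split mixed-sign layers before stacking")
        slabs.append(vals)
    values = np.stack(slabs, axis=2)
    report = {
        "genes_kept": len(genes),
        "samples_kept": len(samples),
        "dropped_genes": {
            lay.name: sorted(set(lay.gene_ids) - set(genes)) for lay in layers
        },
        "dropped_samples": {
            lay.name: sorted(set(lay.sample_ids) - set(samples)) for lay in layers
        },
        "padded_genes": padded,
    }
    cube = DataCube(values=values, gene_ids=genes, sample_ids=samples,
                    layer_names=[lay.name for lay in layers])
    return cube, report


def compute_weights(cube: DataCube) -> WeightTensor:
    """Per-layer weights 1/||X_d||_F^2, broadcast over each slab.

    Layers with less total variance get higher weight, balancing the
    contribution of each data type to the factorization loss.
    """
    sq = np.sum(cube.values ** 2, axis=(0, 1))
    if np.any(sq == 0):
        dead = [n for n, s in zip(cube.layer_names, sq) if s == 0]
        raise ValueError(f"all-zero layer slab(s): {dead}")
    lw = 1.0 / sq
    values = np.broadcast_to(lw, cube.values.shape).copy()
    return WeightTensor(values=values, layer_weights=lw)


def prepare_standard_layers(
    expression: pd.DataFrame | None = None,
    copy_number: pd.DataFrame | None = None,
    mutation: pd.DataFrame | None = None,
    gain_threshold: float = 5.0,
    loss_threshold: float = 1.0,
    sd: str = "population",
) -> list[OmicsLayer]:
    """Run the standard preprocessing pipeline on raw data-type frames.

    Expression is z-scored per gene then sign-split into GE(+)/GE(-);
    copy number is ternarized then split into CN(+)/CN(-); mutation is
    binarized (MT).  Returns the layers in that fixed order, skipping
    absent data types.
    """
    out: list[OmicsLayer] = []
    if expression is not None:
        ge = standardize_expression(
            OmicsLayer.from_frame(expression, "GE", EXPRESSION), sd=sd)
        out.extend(sign_split(ge))
    if copy_number is not None:
        cn = ternarize_copy_number(
            OmicsLayer.from_frame(copy_number, "CN", COPY_NUMBER),
            gain_threshold=gain_threshold, loss_threshold=loss_threshold)
        out.extend(sign_split(cn))
    if mutation is not None:
        out.append(binarize_mutation(OmicsLayer.from_frame(mutation, "MT", MUTATION)))
    return out
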