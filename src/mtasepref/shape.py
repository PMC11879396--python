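"""DNA shape feature tables and their correlation with flanking-context activity.

Shape predictions are consumed, never computed here: tables of per-sequence,
per-position values for the 14 standard descriptors — base-pair parameters
(Shear, Stretch, Stagger, Buckle, ProT, Opening), base-pair-step parameters
(Shift, Slide, Rise, Tilt, Roll, HelT) and the minor-groove features MGW and
EP — are loaded from tab-separated files as exported from a shape-prediction
server.  Step parameters are assigned to the left base of the step for
position labelling.

Position labels run over the flanks (-m..-1, +1..+m) and the target motif
(TSP1..TSPL).  N6-X-N6 tables can be marginalised down to N4-X-N4 by
averaging over the outer bases; intrinsic shape is the unweighted mean over
all contexts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

BP_PARAMS = ["Shear", "Stretch", "Stagger", "Buckle", "ProT", "Opening"]
STEP_PARAMS = ["Shift", "Slide", "Rise", "Tilt", "Roll", "HelT"]
GROOVE_PARAMS = ["MGW", "EP"]
ALL_PARAMS = BP_PARAMS + STEP_PARAMS + GROOVE_PARAMS


def position_labels(motif_len: int, half_width: int, step: bool = False) -> list[str]:
    """Ordered position labels -m..-1, TSP1..TSPL, +1..+m.  Step parameters
    drop the last (rightmost) label: one fewer position than bp parameters."""
    labels = [str(p) for p in range(-half_width, 0)]
    labels += [f"TSP{i}" for i in range(1, motif_len + 1)]
    labels += [f"+{p}" for p in range(1, half_width + 1)]
    return labels[:-1] if step else labels


class ShapeTableError(ValueError):
    """Malformed or incomplete shape table."""


@dataclass
class ShapeTable:
    """Per-sequence per-position shape values.

    ``values``: DataFrame indexed by full context sequence (N_m + motif +
    N_m), columns a MultiIndex (parameter, position label).
    """

    motif: str
    half_width: int
    values: pd.DataFrame

    @property
    def sequences(self) -> list[str]:
        return list(self.values.index)

    @property
    def parameters(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    def validate(self) -> None:
        expected = 4 ** (2 * self.half_width)
        if len(self.values) != expected:
            raise ShapeTableError(
                f"expected {expected} contexts for half-width "
                f"{self.half_width}, found {len(self.values)}"
            )
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)][0]
            raise ShapeTableError(f"missing values in row {bad!r}")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            cols = [f"{p}:{pos}" for p, pos in self.values.columns]
            fh.write(f"# motif={self.motif} half_width={self.half_width}\n")
            fh.write("sequence\t" + "\t".join(cols) + "\n")
            for seq, row in self.values.iterrows():
                fh.write(seq + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


def load_shape_table(path, motif: str) -> ShapeTable:
    """Parse a tab-separated shape table (columns ``parameter:position``).

    Validates completeness: every context of the inferred half-width must be
    present with values for all declared columns; ragged or missing rows
    raise :class:`ShapeTableError` naming the offending row.
    """
    with open(path) as fh:
        header = None
        rows = {}
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                if parts[0] != "sequence":
                    raise ShapeTableError("first column must be 'sequence'")
                header = parts[1:]
                continue
            if len(parts) != len(header) + 1:
                raise ShapeTableError(f"ragged row at line {lineno}: {parts[0]!r}")
            try:
                rows[parts[0]] = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ShapeTableError(
                    f"non-numeric value in row {parts[0]!r}"
                ) from exc
    if header is None or not rows:
        raise ShapeTableError("empty shape table")
    cols = []
    for h in header:
        if ":" not in h:
            raise ShapeTableError(f"column {h!r} is not 'parameter:position'")
        p, pos = h.split(":", 1)
        cols.append((p, pos))
    seq_len = len(next(iter(rows)))
    half_width = (seq_len - len(motif)) // 2
    if seq_len != 2 * half_width + len(motif):
        raise ShapeTableError("sequence length inconsistent with the motif")
    expected = {
        "".join(c[:half_width]) + motif + "".join(c[half_width:])
        for c in product("ACGT", repeat=2 * half_width)
    }
    missing = expected - rows.keys()
    if missing:
        raise ShapeTableError(f"missing context {sorted(missing)[0]!r}")
    values = pd.DataFrame.from_dict(rows, orient="index")
    values.columns = pd.MultiIndex.from_tuples(cols, names=["parameter", "position"])
    values = values.sort_index()
    table = ShapeTable(motif=motif, half_width=half_width, values=values)
    table.validate()
    return table


def marginalize(table: ShapeTable, half_width: int = 4) -> ShapeTable:
    """Average an N_m-X-N_m table down to a smaller half-width by
    marginalising the outer bases (e.g. N6 -> N4)."""
    strip = table.half_width - half_width
    if strip < 0:
        raise ValueError("target half-width exceeds the table's half-width")
    if strip == 0:
        return table
    inner = [s[strip:-strip] for s in table.values.index]
    out = table.values.groupby(pd.Index(inner, name="sequence")).mean()
    # drop positions outside the reduced window
    keep = [
        (p, pos)
        for p, pos in out.columns
        if _position_in_window(pos, half_width)
    ]
    out = out[keep].sort_index()
    return ShapeTable(motif=table.motif, half_width=half_width, values=out)


def _position_in_window(label: str, half_width: int) -> bool:
    if label.startswith("TSP"):
        return True
    return abs(int(label)) <= half_width


def correlate_activity_shape(
    activity: pd.Series, table: ShapeTable
) -> pd.DataFrame:
    """Pearson r between relative activity and each (parameter, position)
    shape feature across all contexts.

    Returns a DataFrame parameters x positions; NaN where a feature is
    constant across contexts.  Raises on context key mismatch.
    """
    if set(activity.index) != set(table.values.index):
        raise ValueError("activity and shape table cover different contexts")
    x = activity.reindex(table.values.index).to_numpy(float)
    mat = table.values.to_numpy(float)
    xc = x - x.mean()
    mc = mat - mat.mean(axis=0)
    sx = np.sqrt((xc**2).sum())
    sm = np.sqrt((mc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ mc) / (sx * sm)
    r[sm == 0] = np.nan
    flat = pd.Series(r, index=table.values.columns)
    return flat.unstack(level="position").reindex(
        index=pd.Index(
            [p for p in ALL_PARAMS if p in flat.index.get_level_values(0)],
            name="parameter",
        )
    )


def intrinsic_shape(table: ShapeTable) -> pd.DataFrame:
    """Unweighted mean shape over all contexts, parameters x positions."""
    means = table.values.mean(axis=0)
    return means.unstack(level="position").reindex(
        index=pd.Index(
            [p for p in ALL_PARAMS if p in means.index.get_level_values(0)],
            name="parameter",
        )
    )


def synthetic_shape_table(
    motif: str,
    half_width: int,
    parameters: list[str] | None = None,
    seed: int = 0,
    activity: pd.Series | None = None,
    linked_parameter: str | None = None,
) -> ShapeTable:
    """Generate a synthetic shape table for testing and demonstration.

    Values are linear functions of the one-hot encoded sequence with
    parameter-specific random weights (so marginal means have a closed form).
    If ``activity`` and ``linked_parameter`` are given, that parameter is an
    affine function of log activity at every position, providing a known
    strongly correlated feature.
    """
    parameters = parameters or ALL_PARAMS
    rng = np.random.default_rng(seed)
    contexts = [
        "".join(c[:half_width]) + motif + "".join(c[half_width:])
        for c in product("ACGT", repeat=2 * half_width)
    ]
    seq_len = 2 * half_width + len(motif)
    onehot = np.zeros((len(contexts), seq_len * 4))
    lut = {b: i for i, b in enumerate("ACGT")}
    for i, s in enumerate(contexts):
        for j, b in enumerate(s):
            onehot[i, j * 4 + lut[b]] = 1.0
    cols = []
    data = []
    for p in parameters:
        is_step = p in STEP_PARAMS
        labels = position_labels(len(motif), half_width, step=is_step)
        if linked_parameter == p:
            if activity is None:
                raise ValueError("linked_parameter requires an activity vector")
            y = np.log(activity.reindex(contexts).to_numpy(float))
            for pos in labels:
                cols.append((p, pos))
                data.append(0.5 + 0.1 * y)
            continue
        for pos in labels:
            w = rng.normal(0, 1, size=seq_len * 4)
            cols.append((p, pos))
            data.append(onehot @ w)
    values = pd.DataFrame(
        np.column_stack(data),
        index=pd.Index(contexts, name="sequence"),
        columns=pd.MultiIndex.from_tuples(cols, names=["parameter", "position"]),
    ).sort_index()
    return ShapeTable(motif=motif, half_width=half_width, values=values)
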