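"""Response-pattern classification of fixed-dose screening readouts.

Three readouts describe each drug at its fixed, clinically relevant
concentration: the residual leukemic bulk (BULK), the within-bulk proportion
of GPR56+/Diff- stem-enriched cells (%LSC) and the proportion of
differentiating cells (%DIFF).  Columns are standardized per readout with
the display convention that higher values mean higher activity: BULK and
%LSC are sign-flipped (fewer bulk cells, fewer LSCs = more active), %DIFF is
not (more differentiation = more active).  Unsupervised agglomerative
clustering of the scaled triples separates cytotoxic, stemness-specific and
differentiating response archetypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

#: scaled readout columns in canonical order, with their label priority
READOUT_COLUMNS = ("bulk", "lsc_prop", "diff_prop")
ARCHETYPE_OF_COLUMN = {"bulk": "cytotoxic", "lsc_prop": "stemness_specific",
                       "diff_prop": "differentiating"}
#: which raw columns are flipped so that larger scaled value = more active
SIGN_FLIPPED = ("bulk", "lsc_prop")


@dataclass
class ScaledActivityMatrix:
    """Drugs x readouts matrix after sign conventions and standardization.

    Each column has mean 0 and unit (sample) variance, except raw-constant
    columns which map to zeros and are listed in ``constant_columns``.
    """

    values: pd.DataFrame
    constant_columns: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(READOUT_COLUMNS):
            raise ValueError(f"columns must be {READOUT_COLUMNS}")


@dataclass
class PatternAssignment:
    drug: str
    label: str
    scaled: tuple
    centroid: tuple


def scale_readouts(raw: pd.DataFrame) -> ScaledActivityMatrix:
    """Standardize raw fixed-dose readouts with the display sign convention.

    ``raw`` is indexed by drug with three columns in the order (bulk, %LSC,
    %DIFF) — e.g. bulk_ratio, prop_lsc, prop_diff.  BULK and %LSC columns
    are negated before per-column standardization (sample SD, ddof=1) so
    that in every column a larger value indicates greater activity.
    """
    if raw.shape[0] < 2:
        raise ValueError("need at least 2 drugs to scale readouts")
    if raw.shape[1] != 3:
        raise ValueError("need exactly 3 readout columns (bulk, %LSC, %DIFF)")
    mat = raw.copy()
    mat.columns = list(READOUT_COLUMNS)
    constant = []
    for col in READOUT_COLUMNS:
        x = mat[col].to_numpy(dtype=float)
        if col in SIGN_FLIPPED:
            x = -x
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            mat[col] = 0.0
            constant.append(col)
        else:
            mat[col] = (x - x.mean()) / sd
    return ScaledActivityMatrix(values=mat, constant_columns=constant)


def _label_clusters(centroids: dict) -> dict:
    """Assign archetype labels to clusters by centroid argmax.

    Column priority (bulk > %LSC > %DIFF) breaks centroid ties.  If two
    clusters claim the same label, the one with the larger coordinate keeps
    it and the other is relabelled by its next-best coordinate.
    """
    cols = list(READOUT_COLUMNS)

    def preference(centroid):
        # columns ordered by coordinate descending, priority-ordered on ties
        return sorted(cols, key=lambda c: (-centroid[c], cols.index(c)))

    prefs = {cid: preference(c) for cid, c in centroids.items()}
    rank = {cid: 0 for cid in centroids}
    labels = {}
    unresolved = sorted(centroids)
    while unresolved:
        claims = {}
        for cid in unresolved:
            col = prefs[cid][min(rank[cid], len(cols) - 1)]
            claims.setdefault(col, []).append(cid)
        next_round = []
        for col, cids in claims.items():
            winner = max(cids, key=lambda cid: centroids[cid][col])
            labels[winner] = ARCHETYPE_OF_COLUMN[col]
            for cid in cids:
                if cid != winner:
                    rank[cid] += 1
                    if rank[cid] >= len(cols):  # more clusters than archetypes
                        labels[cid] = ARCHETYPE_OF_COLUMN[prefs[cid][0]]
                    else:
                        next_round.append(cid)
        unresolved = next_round
    return labels


def cluster_patterns(scaled: ScaledActivityMatrix, k: int = 3,
                     method: str = "ward", metric: str = "euclidean") -> list:
    """Cluster drugs into response archetypes.

    Agglomerative clustering (Ward linkage on Euclidean distance by
    default) cut at ``k`` clusters; rows are processed in sorted drug-id
    order so the result is independent of input row order.  Each cluster is
    labelled by the argmax coordinate of its centroid (bulk -> cytotoxic,
    %LSC -> stemness_specific, %DIFF -> differentiating) with the collision
    rule documented in :func:`_label_clusters`.
    """
    mat = scaled.values.sort_index()
    if k > len(mat):
        raise ValueError(f"k={k} exceeds the number of drugs ({len(mat)})")
    if k == len(mat):
        clusters = np.arange(1, len(mat) + 1)
    else:
        z = linkage(pdist(mat.to_numpy(), metric=metric), method=method)
        clusters = fcluster(z, t=k, criterion="maxclust")
    centroids = {
        cid: mat[clusters == cid].mean().to_dict()
        for cid in np.unique(clusters)
    }
    labels = _label_clusters(centroids)
    out = []
    for drug, cid in zip(mat.index, clusters):
        cent = centroids[cid]
        out.append(PatternAssignment(
            drug=drug, label=labels[cid],
            scaled=tuple(float(v) for v in mat.loc[drug]),
            centroid=tuple(float(cent[c]) for c in READOUT_COLUMNS)))
    return out


def classify_activity(scaled_triple, inactive_threshold: float = 0.5) -> str:
    """Rule-based fallback for a single drug where clustering is undefined.

    Argmax of the scaled (bulk, %LSC, %DIFF) triple, with an "inactive"
    label when every |component| is below ``inactive_threshold``.
    """
    triple = np.asarray(scaled_triple, dtype=float)
    if triple.shape != (3,):
        raise ValueError("expected a scaled triple")
    if np.all(np.abs(triple) < inactive_threshold):
        return "inactive"
    return ARCHETYPE_OF_COLUMN[READOUT_COLUMNS[int(np.argmax(triple))]]


def assignments_frame(assignments: list) -> pd.DataFrame:
    """Tidy view of :func:`cluster_patterns` output."""
    return pd.DataFrame([{
        "drug": a.drug, "label": a.label,
        **{f"scaled_{c}": v for c, v in zip(READOUT_COLUMNS, a.scaled)},
        **{f"centroid_{c}": v for c, v in zip(READOUT_COLUMNS, a.centroid)},
    } for a in assignments])
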