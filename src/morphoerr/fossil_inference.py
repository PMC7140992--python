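"""Classification of unknown specimens and species occurrence-likelihood calls.

Unknown configurations (fossils) are superimposed jointly with the training
specimens, classified with the trained discriminant model, and vetted by
posterior probability: assignments whose maximum group posterior falls below
a threshold (0.95 by default) are dropped.  A species is flagged "likely
present" only when its vetted assignment percentage strictly exceeds the
training set's cross-validated classification error percentage — species
whose share of unknowns falls within the model's own error band are not
trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discriminant import ClassificationResult, LdaModel, predict
from .reporting import build_table1, round_half_away, table3_with_summary

__all__ = [
    "classify_unknowns",
    "occurrence_likelihood",
    "pgm_change",
    "audit_report",
    "SpeciesOccurrence",
    "OccurrenceReport",
    "DatasetAudit",
    "PairAudit",
    "AuditTables",
]


def classify_unknowns(model: LdaModel, X_unknown) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and posterior vectors for unknown specimens.

    The unknowns must live in the training coordinate space (same landmark
    count and superimposition — align them jointly with the training set
    before fitting).
    """
    return predict(model, X_unknown)


@dataclass
class SpeciesOccurrence:
    species: str
    raw_count: int
    vetted_count: int
    vetted_percent: float      # 100 * vetted_count / n_unknowns, unrounded
    likely_present: bool


@dataclass
class OccurrenceReport:
    """Per-species assignment counts and occurrence-likelihood flags."""

    n_unknowns: int
    training_error_percent: float
    threshold: float
    species: list[SpeciesOccurrence]

    @property
    def likely_species(self) -> list[str]:
        return [s.species for s in self.species if s.likely_present]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"species": s.species, "raw_count": s.raw_count,
              "vetted_count": s.vetted_count,
              "vetted_percent": round_half_away(s.vetted_percent, 1),
              "likely_present": s.likely_present}
             for s in self.species]
        )


def occurrence_likelihood(assignments, posteriors, training_error_percent: float,
                          threshold: float = 0.95, species_labels=None,
                          n_unknowns: int | None = None) -> OccurrenceReport:
    """Apply posterior vetting and the occurrence-likelihood criterion.

    Parameters
    ----------
    assignments
        Predicted species label per unknown specimen.
    posteriors
        Either the ``(n, g)`` posterior matrix or the per-specimen maximum
        posterior; specimens below ``threshold`` are vetted (dropped) before
        counts and percentages are computed.
    training_error_percent
        Cross-validated PGM error of the training set, on the 0-100 scale.
    threshold
        Posterior cutoff in (0, 1].

    ``likely_present`` requires the vetted percentage to strictly exceed the
    training error (a species sitting exactly at the error rate is within the
    classification-error band and is not flagged).
    """
    assignments = np.asarray(assignments)
    n = len(assignments) if n_unknowns is None else int(n_unknowns)
    if n <= 0:
        raise ValueError("n_unknowns must be positive")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"posterior threshold must be in (0, 1], got {threshold}")
    if not (0.0 <= training_error_percent <= 100.0):
        raise ValueError("training_error_percent must be in [0, 100]")
    post = np.asarray(posteriors, float)
    max_post = post if post.ndim == 1 else post.max(axis=1)
    if len(max_post) != len(assignments):
        raise ValueError("posteriors and assignments disagree in length")

    if species_labels is None:
        species_labels = sorted(np.unique(assignments))
    else:
        species_labels = list(species_labels)
        unknown = sorted(set(assignments) - set(species_labels))
        if unknown:
            raise ValueError(f"assignments contain labels outside species_labels: {unknown}")

    vetted_mask = max_post >= threshold
    out = []
    for sp in species_labels:
        raw = int(np.sum(assignments == sp))
        vetted = int(np.sum((assignments == sp) & vetted_mask))
        pct = 100.0 * vetted / n
        out.append(SpeciesOccurrence(species=sp, raw_count=raw, vetted_count=vetted,
                                     vetted_percent=pct,
                                     likely_present=pct > training_error_percent))
    return OccurrenceReport(n_unknowns=n, training_error_percent=training_error_percent,
                            threshold=threshold, species=out)


def pgm_change(assign_a, assign_b) -> float:
    """Percent of unknowns whose predicted label differs between two runs.

    Accepts id-keyed mappings/Series (compared by id after checking the id
    sets match) or plain equal-length sequences (compared positionally).
    Returned as a percentage rounded to one decimal, half away from zero.
    """
    a = pd.Series(assign_a)
    b = pd.Series(assign_b)
    if isinstance(assign_a, (dict, pd.Series)) or isinstance(assign_b, (dict, pd.Series)):
        ids_a, ids_b = set(a.index), set(b.index)
        if ids_a != ids_b:
            diff = sorted(map(str, ids_a.symmetric_difference(ids_b)))
            raise ValueError(f"unknown id sets differ: {diff}")
        b = b.reindex(a.index)
    elif len(a) != len(b):
        raise ValueError(f"assignment lengths differ: {len(a)} vs {len(b)}")
    n = len(a)
    if n == 0:
        raise ValueError("no unknowns to compare")
    ndiff = int((a.to_numpy() != b.to_numpy()).sum())
    return round_half_away(100.0 * ndiff / n, 1)


# ---------------------------------------------------------------------------
# Audit summaries shaped like the pairwise and fossil report tables


@dataclass
class DatasetAudit:
    """Per-dataset classification summary used by :func:`audit_report`."""

    name: str
    loocv_error_percent: float
    occurrence: OccurrenceReport | None = None
    assignments: pd.Series | None = None    # unknown id -> predicted species


@dataclass
class PairAudit:
    """One pairwise dataset comparison row."""

    name_a: str
    name_b: str
    error_source: str
    repeatability: float
    r2_percent: float
    pgm_error_change_percent: float
    fossil_pgm_change_percent: float


@dataclass
class AuditTables:
    table1: pd.DataFrame
    table3: pd.DataFrame
    likely_flags: pd.DataFrame


def audit_report(datasets: list[DatasetAudit], pairs: list[PairAudit],
                 species_labels) -> AuditTables:
    """Assemble pairwise (Table-1-shaped) and fossil (Table-3-shaped) summaries.

    The pairwise table carries repeatability, error R2 %, |dPGM error| % and
    fossil PGM change % per comparison with per-source mean rows; the fossil
    table carries vetted per-species counts and training error per dataset
    with Mean and Range summary rows recomputed from its own columns.
    """
    pair_rows = pd.DataFrame(
        [{"comparison": f"{p.name_a}-{p.name_b}", "error_source": p.error_source,
          "repeatability": p.repeatability, "procanova_r2_percent": p.r2_percent,
          "pgm_error_change_percent": p.pgm_error_change_percent,
          "fossil_pgm_change_percent": p.fossil_pgm_change_percent}
         for p in pairs],
        columns=["comparison", "error_source", "repeatability",
                 "procanova_r2_percent", "pgm_error_change_percent",
                 "fossil_pgm_change_percent"],
    )
    table1 = build_table1(pair_rows)

    species_labels = list(species_labels)
    t3_rows, flag_rows = [], []
    for ds in datasets:
        row = {"dataset": ds.name}
        flags = {"dataset": ds.name}
        for sp in species_labels:
            if ds.occurrence is not None:
                occ = next(s for s in ds.occurrence.species if s.species == sp)
                row[sp] = occ.vetted_count
                flags[sp] = occ.likely_present
            else:
                row[sp] = 0
                flags[sp] = False
        row["error_percent"] = ds.loocv_error_percent
        t3_rows.append(row)
        flag_rows.append(flags)
    table3_body = pd.DataFrame(t3_rows, columns=["dataset"] + species_labels + ["error_percent"])
    table3 = table3_with_summary(table3_body, species_labels)
    return AuditTables(table1=table1, table3=table3,
                       likely_flags=pd.DataFrame(flag_rows))
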