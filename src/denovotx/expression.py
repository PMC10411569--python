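"""TPM computation and the expression summaries reported for candidates.

TPM (transcripts per million) normalizes counts by transcript length and
library composition; every library column of a TPM matrix sums to 1e6.
Two expressed-call conventions coexist deliberately: ``any_library``
(max TPM >= 1, inclusive — the pipeline's own acceptance rule) and
``replicate_mean`` (mean TPM strictly > 1 across replicates — the rule
applied to external expression resources).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_tpm",
    "expressed_call",
    "pool_isoforms",
    "summarize_candidates",
    "fraction_annotated_above_candidate_max",
]

EXPRESSED_TPM = 1.0


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Counts (rows = transcripts, columns = libraries) to TPM.

    ``rate = count / length_kb``; ``TPM = rate / sum(rates) * 1e6`` per
    library.  Effective length is the transcript length (the pipeline
    consumes counts, not reads, so no fragment-length correction applies).
    An all-zero library yields an all-zero column.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise KeyError(f"missing lengths for transcripts: {list(missing)[:5]}")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    lens_kb = lengths.reindex(counts.index).astype(float) / 1000.0
    if (lens_kb <= 0).any():
        raise ValueError("transcript lengths must be positive")
    rates = counts.div(lens_kb, axis=0)
    totals = rates.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = rates.div(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def expressed_call(values, mode: str = "any_library", threshold: float = EXPRESSED_TPM) -> bool:
    """Expression call over a set of replicate/library TPM values.

    ``any_library``: max >= threshold (inclusive).  ``replicate_mean``:
    mean strictly > threshold.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty replicate set")
    if mode == "any_library":
        return bool(vals.max() >= threshold)
    if mode == "replicate_mean":
        return bool(vals.mean() > threshold)
    raise ValueError(f"unknown mode {mode!r}")


def pool_isoforms(tpm: pd.DataFrame, isoform_ids) -> pd.Series:
    """Candidate-level per-library TPM: the sum of its isoform TPMs.

    Isoforms absent from the matrix contribute 0.
    """
    isoform_ids = list(isoform_ids)
    if not isoform_ids:
        raise ValueError("candidate has no isoforms")
    present = [i for i in isoform_ids if i in tpm.index]
    if not present:
        return pd.Series(0.0, index=tpm.columns)
    return tpm.loc[present].sum(axis=0)


def summarize_candidates(
    tpm: pd.DataFrame,
    candidates: dict[str, list[str]],
    threshold: float = EXPRESSED_TPM,
) -> tuple[pd.DataFrame, dict]:
    """Per-candidate expression summaries plus cohort statistics.

    ``candidates`` maps candidate id -> isoform transcript ids.  Candidate
    TPM in a library pools (sums) isoforms.  Per candidate: number of
    libraries at TPM >= threshold, number nonzero, max TPM, and the mean
    of observations at TPM >= threshold (NaN if never expressed).  Cohort
    stats: the mean TPM over all expressed observations pooled across
    candidates, and the mean number of nonzero libraries.
    """
    rows = []
    expressed_obs: list[float] = []
    for cid in sorted(candidates):
        pooled = pool_isoforms(tpm, candidates[cid])
        vals = pooled.values.astype(float)
        expr = vals[vals >= threshold]
        expressed_obs.extend(expr.tolist())
        rows.append(
            {
                "candidate_id": cid,
                "n_libraries_expressed": int((vals >= threshold).sum()),
                "n_libraries_nonzero": int((vals > 0).sum()),
                "max_TPM": float(vals.max()) if vals.size else 0.0,
                "mean_TPM_of_expressed": float(expr.mean()) if expr.size else float("nan"),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "candidate_id",
            "n_libraries_expressed",
            "n_libraries_nonzero",
            "max_TPM",
            "mean_TPM_of_expressed",
        ],
    )
    if len(df):
        cohort = {
            "mean_tpm_of_expressed_obs": float(np.mean(expressed_obs)) if expressed_obs else float("nan"),
            "mean_n_libraries_nonzero": float(df["n_libraries_nonzero"].mean()),
            "mean_n_libraries_expressed": float(df["n_libraries_expressed"].mean()),
            "max_tpm": float(df["max_TPM"].max()),
            "defined": True,
        }
    else:
        cohort = {"defined": False}
    return df, cohort


def fraction_annotated_above_candidate_max(
    tpm: pd.DataFrame,
    annotated_ids,
    candidate_ids,
    library: str | None = None,
):
    """Per library: fraction of annotated genes with TPM above the maximum
    TPM observed among candidates in that library.

    With ``library`` given returns a float; otherwise a Series over all
    libraries.  Candidate TPM rows absent from the matrix count as 0.
    """
    annotated_ids = [i for i in annotated_ids if i in tpm.index]
    if not annotated_ids or not list(candidate_ids):
        raise ValueError("need at least one annotated gene and one candidate")
    cand_rows = tpm.reindex(list(candidate_ids)).fillna(0.0)
    ann_rows = tpm.loc[annotated_ids]
    cand_max = cand_rows.max(axis=0)
    frac = (ann_rows.gt(cand_max, axis=1)).sum(axis=0) / len(annotated_ids)
    if library is not None:
        return float(frac[library])
    return frac
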