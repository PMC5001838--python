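"""Evolutionary-coupling inference by pseudo-likelihood Potts-model fitting.

A global pairwise (Potts) model over the 21-state alphabet (20 amino acids +
gap) is fit to a reweighted alignment by maximising the L2-regularised
pseudo-likelihood — the weighted sum over sites of the conditional
log-likelihood of each column given the rest of the sequence — with a
symmetric coupling parameterisation.  The objective is convex, so the fit is
deterministic up to optimiser tolerance.

Pair scores are Frobenius norms of the coupling blocks in the zero-sum gauge,
taken over the 20 non-gap states, with the average-product correction (APC)
applied by default.  Scored pairs are then calibrated against structural
contact maps: cumulative precision of the non-local intra-domain pairs, in
rank order, determines the deepest rank still meeting a precision target
(80% by default), and every retained pair above that rank is selected —
including inter-domain pairs, which are what the calibration is for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .msa import GAP, Q, LabeledMSA

N_AA = Q - 1  # non-gap states


class ConvergenceError(RuntimeError):
    """PLM optimisation failed to reach the gradient tolerance."""

    def __init__(self, message: str, grad_norm: float):
        super().__init__(message)
        self.grad_norm = grad_norm


@dataclass
class PottsModel:
    """Fields ``h`` (L, q) and symmetric couplings ``J`` (L, L, q, q).

    ``J[i, j]`` is the q-by-q block coupling columns *i* and *j*;
    ``J[j, i] == J[i, j].T`` and diagonal blocks are zero.  ``positions``
    records the original alignment column of each model site.
    """

    h: np.ndarray
    J: np.ndarray
    lambda_h: float
    lambda_J: float
    positions: np.ndarray

    @property
    def L(self) -> int:
        return self.h.shape[0]


def _objective(x, Z, codes, w, H_shape, L, q, lam_h, lam_j_el, neff):
    nLq = L * q
    H = x[:nLq].reshape(L, q)
    W = x[nLq:].reshape(nLq, nLq)
    S = 0.5 * (W + W.T)
    # zero the diagonal blocks (no self couplings)
    S4 = S.reshape(L, q, L, q)
    idx = np.arange(L)
    S4[idx, :, idx, :] = 0.0
    S = S4.reshape(nLq, nLq)

    logits = (Z @ S).reshape(-1, L, q) + H[None, :, :]
    lse = logsumexp(logits, axis=2)
    n = Z.shape[0]
    rows = np.arange(n)[:, None]
    cols = np.arange(L)[None, :]
    ll = logits[rows, cols, codes] - lse
    f = -(w @ ll.sum(axis=1)) / neff
    f += lam_h * np.sum(H * H) + lam_j_el * np.sum(S * S)

    P = np.exp(logits - lse[:, :, None])
    D = P
    D[rows, cols, codes] -= 1.0
    D *= (w / neff)[:, None, None]
    gH = D.sum(axis=0) + 2.0 * lam_h * H
    GS = Z.T @ D.reshape(n, nLq)
    GS += 2.0 * lam_j_el * S
    GS4 = GS.reshape(L, q, L, q)
    GS4[idx, :, idx, :] = 0.0
    GS = GS4.reshape(nLq, nLq)
    gW = 0.5 * (GS + GS.T)
    return f, np.concatenate([gH.ravel(), gW.ravel()])


def fit_plm(
    msa: LabeledMSA,
    lambda_h: float = 0.01,
    lambda_J: float | None = None,
    max_iter: int = 500,
    grad_tol: float = 1e-3,
) -> PottsModel:
    """Fit the Potts model by weighted, L2-regularised pseudo-likelihood.

    ``lambda_J`` defaults to ``0.01 * (L - 1)``; internally the coupling
    penalty per matrix element is ``lambda_J / (L - 1)`` so the default
    matches the field penalty in scale.  The (convex) objective is minimised
    with L-BFGS; exceeding ``max_iter`` without meeting ``grad_tol``
    (projected-gradient infinity norm) raises :class:`ConvergenceError`
    carrying the final gradient norm.
    """
    if msa.weights is None:
        raise ValueError("alignment must carry weights; run compute_weights first")
    codes = msa.encoded().astype(np.int64)
    n, L = codes.shape
    if lambda_J is None:
        lambda_J = 0.01 * max(L - 1, 1)
    lam_j_el = lambda_J / max(L - 1, 1)  # single column: fields only, J empty
    w = np.asarray(msa.weights, dtype=float)
    neff = w.sum()
    Z = np.zeros((n, L * Q))
    Z[np.repeat(np.arange(n), L), (np.arange(L) * Q)[None, :].repeat(n, 0).ravel() + codes.ravel()] = 1.0

    x0 = np.zeros(L * Q + (L * Q) ** 2)
    res = minimize(
        _objective,
        x0,
        args=(Z, codes, w, (L, Q), L, Q, lambda_h, lam_j_el, neff),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": max_iter, "maxfun": 4 * max_iter, "ftol": 1e-10, "gtol": grad_tol},
    )
    gnorm = float(np.max(np.abs(res.jac)))
    if not res.success and gnorm > grad_tol:
        raise ConvergenceError(
            f"PLM fit did not converge in {max_iter} iterations "
            f"(final projected gradient norm {gnorm:.3e})",
            grad_norm=gnorm,
        )
    nLq = L * Q
    H = res.x[:nLq].reshape(L, Q)
    W = res.x[nLq:].reshape(nLq, nLq)
    S = 0.5 * (W + W.T)
    J = S.reshape(L, Q, L, Q).transpose(0, 2, 1, 3).copy()
    idx = np.arange(L)
    J[idx, idx] = 0.0
    return PottsModel(
        h=H, J=J, lambda_h=lambda_h, lambda_J=lambda_J,
        positions=msa.columns.copy(),
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def zero_sum_gauge(block: np.ndarray) -> np.ndarray:
    """Double-centre a coupling block so every row and column sums to zero."""
    return (
        block
        - block.mean(axis=0, keepdims=True)
        - block.mean(axis=1, keepdims=True)
        + block.mean()
    )


def apc_correct(fn: np.ndarray) -> np.ndarray:
    """Average-product correction on a symmetric score matrix (diag ignored)."""
    L = fn.shape[0]
    off = ~np.eye(L, dtype=bool)
    if not np.any(fn[off]):
        return np.zeros_like(fn)
    row_mean = fn.sum(axis=1) / (L - 1)
    overall = fn[off].mean()
    corr = fn - np.outer(row_mean, row_mean) / overall
    np.fill_diagonal(corr, 0.0)
    return corr


@dataclass
class CouplingTable:
    """Ranked residue-pair coupling scores with locality/position flags."""

    pairs: pd.DataFrame  # columns: i, j, raw_score, score, rank, is_nonlocal, in_range, truth

    def __post_init__(self) -> None:
        df = self.pairs
        if not (df["rank"].sort_values().values == np.arange(1, len(df) + 1)).all():
            raise ValueError("ranks must be a permutation of 1..n")
        ordered = df.sort_values("rank")["score"].values
        if np.any(np.diff(ordered) > 1e-12):
            raise ValueError("scores must be non-increasing in rank")

    def write_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False, float_format="%.6g")


def score_couplings(
    model: PottsModel,
    apc: bool = True,
    min_separation: int = 5,
    max_position: int = 400,
) -> CouplingTable:
    """Frobenius-norm pair scores (zero-sum gauge, non-gap states, APC).

    Raw (pre-APC) norms are kept alongside the ranked score.  The locality
    flag marks pairs more than ``min_separation`` positions apart and the
    range flag pairs with both positions at most ``max_position`` (couplings
    beyond are dominated by gap signal in the source alignments).
    """
    L = model.L
    fn = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            block = zero_sum_gauge(model.J[i, j][:N_AA, :N_AA])
            fn[i, j] = fn[j, i] = np.sqrt(np.sum(block * block))
    scores = apc_correct(fn) if apc else fn
    iu, ju = np.triu_indices(L, k=1)
    pos = np.asarray(model.positions)
    df = pd.DataFrame(
        {
            "i": pos[iu],
            "j": pos[ju],
            "raw_score": fn[iu, ju],
            "score": scores[iu, ju],
        }
    )
    df = df.sort_values(["score", "i", "j"], ascending=[False, True, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["is_nonlocal"] = (df["j"] - df["i"]).abs() > min_separation
    df["in_range"] = (df["i"] <= max_position) & (df["j"] <= max_position)
    df["truth"] = "unscorable"
    return CouplingTable(pairs=df)


# ---------------------------------------------------------------------------
# precision calibration against structural contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactTruth:
    """Contact evidence from one structure, in that structure's numbering.

    ``pairs`` holds (min(r1, r2), max(r1, r2)) residue-number tuples below the
    contact cutoff; ``resolved`` the residue numbers present in the structure;
    ``domain_of`` an optional residue -> domain-label map used to separate
    intra- from inter-domain pairs.
    """

    structure_id: str
    pairs: set[tuple[int, int]]
    resolved: set[int]
    domain_of: Mapping[int, str] | None = None


@dataclass
class PrecisionResult:
    threshold_rank: int
    selected: pd.DataFrame
    curve: pd.DataFrame  # rank, i, j, kind, truth, cum_precision
    table: CouplingTable


def annotate_truth(
    table: CouplingTable,
    contacts: Sequence[ContactTruth],
    position_maps: Sequence[Mapping[int, int]] | None = None,
) -> CouplingTable:
    """Label each pair true/false/unscorable against the supplied structures.

    A pair is **true** when its mapped residues are closer than the contact
    cutoff in at least one structure, **false** when mappable somewhere but
    never in contact, and **unscorable** when no structure resolves both
    residues.  ``position_maps`` translate alignment columns into each
    structure's residue numbering (identity by default).
    """
    if position_maps is None:
        position_maps = [None] * len(contacts)
    truth = []
    kind = []
    for i, j in zip(table.pairs["i"], table.pairs["j"]):
        label = "unscorable"
        pair_kind = "unknown"
        for ct, pmap in zip(contacts, position_maps):
            ri = pmap.get(i) if pmap is not None else i
            rj = pmap.get(j) if pmap is not None else j
            if ri is None or rj is None:
                continue
            if ri not in ct.resolved or rj not in ct.resolved:
                continue
            if pair_kind == "unknown" and ct.domain_of is not None:
                da, db = ct.domain_of.get(ri), ct.domain_of.get(rj)
                if da is not None and db is not None:
                    pair_kind = "intra" if da == db else "inter"
            key = (min(ri, rj), max(ri, rj))
            if key in ct.pairs:
                label = "true_contact"
                break
            label = "false_contact"
        truth.append(label)
        if pair_kind == "unknown":
            pair_kind = "intra"  # no domain info: treat as intra-domain
        kind.append(pair_kind)
    df = table.pairs.copy()
    df["truth"] = truth
    df["kind"] = kind
    return CouplingTable(pairs=df)


def calibrate_precision(
    table: CouplingTable,
    contacts: Sequence[ContactTruth],
    position_maps: Sequence[Mapping[int, int]] | None = None,
    min_separation: int = 5,
    max_position: int = 400,
    precision_target: float = 0.8,
    interdomain_in_denominator: bool = False,
    rule: str = "largest",
) -> PrecisionResult:
    """Select couplings by the precision of intra-domain pairs.

    Pairs failing the locality (|i - j| > ``min_separation``) or position
    (both <= ``max_position``) filters are discarded.  Cumulative precision is
    computed in rank order over the evaluable intra-domain pairs (inter-domain
    pairs enter the denominator only with ``interdomain_in_denominator``);
    ``threshold_rank`` is the largest retained rank whose cumulative precision
    meets the target (``rule="first"`` instead stops at the last rank before
    precision first drops below the target).  All retained pairs at or above
    the threshold are selected.
    """
    ann = annotate_truth(table, contacts, position_maps)
    df = ann.pairs
    retained = df[
    ((df["j"] - df["i"]).abs() > min_separation)
        & (df["i"] <= max_position)
        & (df["j"] <= max_position)
    ].sort_values("rank").reset_index(drop=True)
    if retained.empty:
        raise ValueError("no pairs survive the locality/position filters")
    counted = (retained["truth"] != "unscorable") & (
        (retained["kind"] == "intra") | interdomain_in_denominator
    )
    if not counted.any():
        raise ValueError("no evaluable intra-domain pairs; cannot calibrate precision")
    cum_true = np.cumsum((retained["truth"] == "true_contact") & counted)
    cum_eval = np.cumsum(counted)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(cum_eval > 0, cum_true / cum_eval, np.nan)
    retained = retained.assign(
        retained_rank=np.arange(1, len(retained) + 1), cum_precision=precision
    )
    ok = np.flatnonzero(np.nan_to_num(precision, nan=1.0) >= precision_target)
    meets = np.nan_to_num(precision, nan=1.0) >= precision_target
    if rule == "largest":
        threshold = int(ok[-1]) + 1 if ok.size else 0
    elif rule == "first":
        below = np.flatnonzero(~meets)
        threshold = len(retained) if below.size == 0 else int(below[0])
    else:
        raise ValueError(f"unknown threshold rule '{rule}'")
    selected = retained[retained["retained_rank"] <= threshold].copy()
    curve = retained[
        ["retained_rank", "rank", "i", "j", "score", "kind", "truth", "cum_precision"]
    ]
    return PrecisionResult(
        threshold_rank=threshold, selected=selected, curve=curve, table=ann
    )
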