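"""Weighted animal-model association between carrier dosage and breeding values.

The model regresses deregressed breeding values (DEBV) on the count of
the detrimental allele:

    y_ij = mu + R * dosage_i + a_j + e_ij

with a random additive genetic effect a ~ N(0, A sigma_a^2) under the
pedigree numerator relationship matrix A, and heteroscedastic residuals
e_ij ~ N(0, sigma_e^2 / w_ij) with per-record weights w.  Variance
components enter as the ratio sigma_a^2 / sigma_e^2 (taken from the
routine evaluation's heritability rather than re-estimated); sigma_e^2
is profiled out from the generalized residual sum of squares.  The
dosage effect is tested with a Wald z statistic; effects with
-log10(P) > 5 are declared significant.

The mixed-model equations are assembled sparsely using Henderson's
rules for the inverse relationship matrix (inbreeding-aware, with
inbreeding coefficients from the Meuwissen-Luo algorithm), which keeps
fits with tens of thousands of animals cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.stats import norm

UNKNOWN = -1
LOG10 = np.log(10.0)


@dataclass
class Pedigree:
    """Topologically ordered pedigree: parents precede offspring.

    ``sire``/``dam`` hold row indices into ``animals`` or ``-1`` for an
    unknown parent.
    """

    animals: list[str]
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.animals)
        if len(self.sire) != n or len(self.dam) != n:
            raise ValueError("parent arrays must match the animal list")
        order = np.arange(n)
        if np.any(self.sire >= order) or np.any(self.dam >= order):
            raise ValueError("pedigree not topologically sorted: a parent follows its offspring")

    def __len__(self) -> int:
        return len(self.animals)

    @property
    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.animals)}

    @classmethod
    def from_triples(cls, triples: Iterable[tuple[str, str | None, str | None]]) -> "Pedigree":
        """Build from (animal, sire, dam) rows, sorting topologically.

        Unknown parents are None/empty/"0"; parents referenced but never
        listed as animals are added as founders.  Cycles raise.
        """
        rows = [(str(a), _norm(s), _norm(d)) for a, s, d in triples]
        known = {a for a, _, _ in rows}
        parents_only = [p for _, s, d in rows for p in (s, d)
                        if p is not None and p not in known]
        all_rows = [(p, None, None) for p in dict.fromkeys(parents_only)] + rows
        parent_map = {a: (s, d) for a, s, d in all_rows}
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(a: str) -> None:
            stack = [(a, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    state[node] = 2
                    order.append(node)
                    continue
                if state.get(node) == 2:
                    continue
                if state.get(node) == 1:
                    raise ValueError(f"pedigree cycle involving {node}")
                state[node] = 1
                stack.append((node, True))
                for p in parent_map[node]:
                    if p is not None and state.get(p) != 2:
                        stack.append((p, False))

        for a, _, _ in all_rows:
            visit(a)
        idx = {a: i for i, a in enumerate(order)}
        sire = np.array([idx[parent_map[a][0]] if parent_map[a][0] else UNKNOWN
                         for a in order], dtype=np.int64)
        dam = np.array([idx[parent_map[a][1]] if parent_map[a][1] else UNKNOWN
                        for a in order], dtype=np.int64)
        return cls(order, sire, dam)

    def prune_to(self, keep: Iterable[str]) -> "Pedigree":
        """Restrict to the given animals plus all their ancestors."""
        idx = self.index
        wanted = np.zeros(len(self), dtype=bool)
        stack = [idx[a] for a in keep if a in idx]
        while stack:
            i = stack.pop()
            if wanted[i]:
                continue
            wanted[i] = True
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN:
                    stack.append(int(p))
        sel = np.flatnonzero(wanted)
        remap = {int(old): new for new, old in enumerate(sel)}
        return Pedigree(
            [self.animals[i] for i in sel],
            np.array([remap.get(int(self.sire[i]), UNKNOWN) for i in sel]),
            np.array([remap.get(int(self.dam[i]), UNKNOWN) for i in sel]))


def _norm(p) -> str | None:
    if p is None:
        return None
    p = str(p).strip()
    return None if p in ("", "0", "nan", "None", ".") else p


def build_a_matrix(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    Founders have diagonal 1 (unknown parents are unrelated and
    non-inbred); a(i, j) = 0.5 * (a(j, s_i) + a(j, d_i)) and
    a(i, i) = 1 + 0.5 * a(s_i, d_i).
    """
    n = len(pedigree)
    a = np.zeros((n, n))
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * a[s, :i]
        if d != UNKNOWN:
            row += 0.5 * a[d, :i]
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[s, d] if s != UNKNOWN and d != UNKNOWN else 0.0)
    return a


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo recursion (A = L D L')."""
    n = len(pedigree)
    sire, dam = pedigree.sire, pedigree.dam
    f = np.zeros(n)
    d = np.zeros(n)  # within-family (Mendelian sampling) variance terms
    for i in range(n):
        s, t = sire[i], dam[i]
        fs = f[s] if s != UNKNOWN else -1.0
        ft = f[t] if t != UNKNOWN else -1.0
        d[i] = 0.5 - 0.25 * (fs + ft)
        if s == UNKNOWN and t == UNKNOWN:
            f[i] = 0.0
            continue
        # accumulate L-row contributions over ancestors
        contrib = np.zeros(i + 1)
        if s != UNKNOWN:
            contrib[s] += 0.5
        if t != UNKNOWN:
            contrib[t] += 0.5
        aii = 0.0
        for j in range(i - 1, -1, -1):
            c = contrib[j]
            if c == 0.0:
                continue
            aii += c * c * d[j]
            if sire[j] != UNKNOWN:
                contrib[sire[j]] += 0.5 * c
            if dam[j] != UNKNOWN:
                contrib[dam[j]] += 0.5 * c
        # a(i,i) = sum_j L_ij^2 D_j; the own term L_ii^2 D_i = d[i]
        f[i] = aii + d[i] - 1.0
    return f


def build_a_inverse(pedigree: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse relationship matrix by Henderson's rules with inbreeding."""
    n = len(pedigree)
    f = inbreeding_coefficients(pedigree)
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = int(pedigree.sire[i]), int(pedigree.dam[i])
        fs = f[s] if s != UNKNOWN else -1.0
        fd = f[d] if d != UNKNOWN else -1.0
        alpha = 1.0 / (0.5 - 0.25 * (fs + fd))
        entries = [(i, i, alpha)]
        for p in (s, d):
            if p != UNKNOWN:
                entries += [(i, p, -alpha / 2), (p, i, -alpha / 2), (p, p, alpha / 4)]
        if s != UNKNOWN and d != UNKNOWN:
            entries += [(s, d, alpha / 4), (d, s, alpha / 4)]
        for r, c, v in entries:
            rows.append(r)
            cols.append(c)
            vals.append(v)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


@dataclass
class AnimalModelFit:
    mu_hat: float
    effect: float
    effect_se: float
    wald_p: float
    minus_log10_p: float
    additive_variance_ratio: float
    sigma_e2: float
    n_records: int
    n_carriers: int
    n_noncarriers: int

    @property
    def significant(self) -> bool:
        return self.minus_log10_p > 5.0


def fit_animal_model(records: pd.DataFrame, pedigree: Pedigree,
                     additive_variance_ratio: float) -> AnimalModelFit:
    """Solve the weighted mixed-model equations for the carrier-dosage effect.

    ``records`` needs columns animal, debv, weight, dosage.
    ``additive_variance_ratio`` is sigma_a^2 / sigma_e^2; a ratio of 0
    collapses the model to weighted least squares.
    """
    records = records.reset_index(drop=True)
    if records["animal"].duplicated().any():
        raise ValueError("animals must appear once in the trait records")
    dosage = records["dosage"].to_numpy(dtype=float)
    if len(np.unique(dosage)) < 2:
        raise ValueError("carrier dosage is constant; fixed-effects design singular")
    y = records["debv"].to_numpy(dtype=float)
    w = records["weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    nrec = len(records)
    x = np.column_stack([np.ones(nrec), dosage])
    p = x.shape[1]

    if additive_variance_ratio <= 0:
        xtwx = x.T @ (w[:, None] * x)
        xtwy = x.T @ (w * y)
        c11 = np.linalg.inv(xtwx)
        beta = c11 @ xtwy
        dof = nrec - p
        sigma_e2 = float((y @ (w * y) - beta @ xtwy) / dof)
    else:
        ped = pedigree.prune_to(records["animal"])
        idx = ped.index
        try:
            animal_idx = np.array([idx[a] for a in records["animal"]])
        except KeyError as exc:
            raise ValueError(f"animal {exc} missing from pedigree") from exc
        nanim = len(ped)
        z = sparse.coo_matrix((np.ones(nrec), (np.arange(nrec), animal_idx)),
                              shape=(nrec, nanim)).tocsr()
        ainv = build_a_inverse(ped)
        xs = sparse.csr_matrix(x)
        dmat = sparse.diags(w)
        top = sparse.hstack([xs.T @ dmat @ xs, xs.T @ dmat @ z])
        bottom = sparse.hstack([z.T @ dmat @ xs,
                                z.T @ dmat @ z + ainv / additive_variance_ratio])
        coeff = sparse.vstack([top, bottom]).tocsc()
        rhs = np.concatenate([x.T @ (w * y), z.T @ (w * y)])
        lu = splu(coeff)
        theta = lu.solve(rhs)
        beta = theta[:p]
        # C11 block of the inverse coefficient matrix = (X' V*^-1 X)^-1
        eye = np.zeros((p + nanim, p))
        eye[:p, :p] = np.eye(p)
        c_cols = lu.solve(eye)
        c11 = c_cols[:p, :p]
        dof = nrec - p
        sigma_e2 = float((y @ (w * y) - theta @ rhs) / dof)

    var_beta = sigma_e2 * c11
    se = float(np.sqrt(var_beta[1, 1]))
    zstat = beta[1] / se
    log_p = np.log(2.0) + norm.logsf(abs(zstat))
    wald_p = float(np.exp(log_p))
    return AnimalModelFit(
        mu_hat=float(beta[0]), effect=float(beta[1]), effect_se=se,
        wald_p=wald_p, minus_log10_p=float(-log_p / LOG10),
        additive_variance_ratio=additive_variance_ratio, sigma_e2=sigma_e2,
        n_records=nrec,
        n_carriers=int((dosage >= 1).sum()),
        n_noncarriers=int((dosage == 0).sum()))


def filter_trait_records(records: pd.DataFrame,
                         min_reliability: float = 0.20) -> pd.DataFrame:
    """Apply the DEBV quality filters: weight > 0 and reliability > 0.20."""
    keep = (records["weight"] > 0) & (records["reliability"] > min_reliability)
    return records.loc[keep].reset_index(drop=True)


def run_association(traits: Mapping[str, pd.DataFrame],
                    carriers: "CarrierStatusLike",
                    pedigree: Pedigree,
                    heritability: Mapping[str, float] | float,
                    min_records: int = 100) -> pd.DataFrame:
    """Fit every trait and report effects in a per-trait table.

    ``traits`` maps trait name to a frame with columns animal, debv,
    reliability, weight.  ``heritability`` gives h^2 per trait (or one
    value for all); the variance ratio is h^2 / (1 - h^2).  Traits with
    fewer than ``min_records`` retained animals, no carriers, or a
    constant dosage are skipped with a warning.
    """
    dosage_of = carriers.dosage if hasattr(carriers, "dosage") else dict(carriers)
    rows = []
    for trait, frame in traits.items():
        kept = filter_trait_records(frame)
        kept = kept[kept["animal"].isin(dosage_of)].copy()
        kept["dosage"] = kept["animal"].map(dosage_of)
        if len(kept) < min_records:
            warnings.warn(f"trait {trait}: only {len(kept)} retained records, skipped")
            continue
        if kept["dosage"].nunique() < 2 or (kept["dosage"] >= 1).sum() == 0:
            warnings.warn(f"trait {trait}: no carrier contrast, skipped")
            continue
        h2 = heritability[trait] if isinstance(heritability, Mapping) else float(heritability)
        fit = fit_animal_model(kept, pedigree, additive_variance_ratio=h2 / (1.0 - h2))
        rows.append({
            "trait": trait,
            "n_noncarriers": fit.n_noncarriers,
            "n_carriers": fit.n_carriers,
            "effect": fit.effect,
            "se": fit.effect_se,
            "minus_log10_p": fit.minus_log10_p,
            "significant": fit.significant,
        })
    return pd.DataFrame(rows, columns=["trait", "n_noncarriers", "n_carriers",
                                       "effect", "se", "minus_log10_p", "significant"])
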