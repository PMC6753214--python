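"""Stage 2 — factor analysis to thin out collinear candidates.

Candidates that load together on a common factor are near-collinear;
keeping all of them destabilizes multivariable fits, so only the member
with the largest absolute loading survives into the selection stage.

Extraction is principal-component analysis of the candidates' correlation
matrix with Kaiser retention (eigenvalue > 1) and varimax rotation — the
workhorse convention in the clinical-questionnaire literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tabular_io import Cohort

DEFAULT_LOADING_THRESHOLD = 0.6


def bartlett_sphericity(corr: np.ndarray, n: int) -> float:
    """P-value of Bartlett's test that a correlation matrix is identity.

    Factor analysis is only meaningful when the candidates are correlated
    at all; on an identity-like matrix the extracted factors are sampling
    noise and would group unrelated variables.
    """
    p = corr.shape[0]
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0:
        return 0.0
    stat = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    return float(stats.chi2.sf(stat, df))


def bartlett_factor_count(eigval: np.ndarray, n: int, alpha: float = 0.05) -> int:
    """Number of factors by Bartlett's sequential eigenvalue-equality test.

    Retains the smallest k for which the hypothesis "the last p - k
    eigenvalues are equal" (pure noise beyond k factors) is not rejected
    at `alpha`.  Unlike the Kaiser rule this accounts for sampling
    spread: on an identity-like sample correlation matrix it retains no
    factors instead of factoring noise.
    """
    eigval = np.sort(np.asarray(eigval, float))[::-1]
    p = len(eigval)
    for k in range(p - 1):
        lam = np.clip(eigval[k:], 1e-12, None)
        q = p - k
        stat = (n - 1 - (2 * p + 5) / 6.0 - 2 * k / 3.0) * (
            q * np.log(lam.mean()) - np.sum(np.log(lam))
        )
        df = (q + 2) * (q - 1) / 2.0
        if stats.chi2.sf(stat, df) >= alpha:
            return k
    return p - 1


@dataclass
class FactorGroup:
    index: int
    members: dict[str, float]      # name -> loading on this factor
    representative: str

    def __post_init__(self):
        if not self.members:
            raise ValueError("empty factor group")
        if self.representative not in self.members:
            raise ValueError("representative must be a group member")


def varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Orthogonal varimax rotation of a loading matrix.

    Convergence of the SVD iteration is slow near simple structure, hence
    the generous iteration cap.
    """
    p, k = loadings.shape
    if k < 2:
        return loadings.copy()
    rot = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - (lam * np.mean(lam**2, axis=0)))
        )
        rot = u @ vt
        new_var = s.sum()
        if var != 0 and new_var / var < 1 + tol:
            break
        var = new_var
    return loadings @ rot


def factor_decompose(
    cohort: Cohort,
    candidates: list[str],
    loading_threshold: float = DEFAULT_LOADING_THRESHOLD,
    retention: str | int = "bartlett",
    retention_alpha: float = 0.05,
) -> list[FactorGroup]:
    """Group candidates by their rotated factor loadings.

    The factor count defaults to Bartlett's sequential eigenvalue test
    (``retention="bartlett"``); the Kaiser rule (eigenvalue > 1) and an
    explicit integer count are also available.  A candidate joins the
    factor on which its absolute loading is largest, provided that
    loading reaches `loading_threshold`; otherwise it forms a singleton
    group (no collinearity concern).  With no retained factor every
    candidate is a singleton.
    """
    if len(candidates) < 2:
        return [
            FactorGroup(index=-1 - i, members={c: 1.0}, representative=c)
            for i, c in enumerate(candidates)
        ]
    data = cohort.complete_cases(candidates)[candidates].to_numpy(dtype=float)
    n = data.shape[0]
    sds = data.std(axis=0, ddof=1)
    for name, sd in zip(candidates, sds):
        if sd == 0:
            raise ValueError(f"candidate {name!r} is constant; cannot enter factor analysis")
    if n <= len(candidates):
        warnings.warn(
            f"factor analysis with {len(candidates)} candidates but only {n} complete rows",
            stacklevel=2,
        )
    corr = np.corrcoef(data, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if retention == "bartlett":
        m = bartlett_factor_count(eigval, n, alpha=retention_alpha)
    elif retention == "kaiser":
        m = int((eigval > 1.0).sum())
    else:
        m = int(retention)
    m = max(min(m, len(candidates)), 0)

    groups: list[FactorGroup] = []
    assigned: dict[str, tuple[int, float]] = {}
    if m > 0:
        load = eigvec[:, :m] * np.sqrt(np.clip(eigval[:m], 0, None))
        load = varimax(load)
        # deterministic sign: flip each factor so its largest |loading| is positive
        for j in range(m):
            i_max = int(np.argmax(np.abs(load[:, j])))
            if load[i_max, j] < 0:
                load[:, j] *= -1
        for i, name in enumerate(candidates):
            j = int(np.argmax(np.abs(load[i])))
            if abs(load[i, j]) >= loading_threshold:
                assigned[name] = (j, float(load[i, j]))
        for j in range(m):
            members = {nm: ld for nm, (jj, ld) in assigned.items() if jj == j}
            if members:
                rep = max(sorted(members), key=lambda nm: abs(members[nm]))
                groups.append(FactorGroup(index=j, members=members, representative=rep))
    for i, name in enumerate(candidates):
        if name not in assigned:
            groups.append(FactorGroup(index=-1 - i, members={name: 1.0}, representative=name))
    return groups


def pick_representatives(
    groups: list[FactorGroup], bivariable_p: dict[str, float] | None = None
) -> list[str]:
    """One candidate per factor group: the largest |loading| wins.

    Loading ties are broken by the smaller bivariable screening p-value
    (when supplied), then lexicographically.
    """
    reps = []
    for g in groups:
        if not g.members:
            raise ValueError("empty factor group")
        best = sorted(
            g.members,
            key=lambda nm: (
                -abs(g.members[nm]),
                bivariable_p.get(nm, 1.0) if bivariable_p else 1.0,
                nm,
            ),
        )[0]
        reps.append(best)
    return reps


def loadings_frame(groups: list[FactorGroup]):
    """Long-format loading table (factor, member, loading, representative)."""
    import pandas as pd

    rows = [
        {"factor": g.index, "member": nm, "loading": ld, "representative": nm == g.representative}
        for g in groups
        for nm, ld in g.members.items()
    ]
    return pd.DataFrame(rows)
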