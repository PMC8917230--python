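"""Linear least-squares fitting of m6A-U helix stack parameters.

Fully helical duplexes containing m6A-U pairs are turned into a linear
system: for each duplex the fixed nearest-neighbor terms (Watson-Crick and
G-U stacks, duplex initiation, terminal A-U penalties where needed, the
symmetry correction for self-complementary duplexes) are subtracted from
the experimental dG37, and the residual stability is modelled as integer
counts of the 15 m6A-U stack contexts times their unknown free energies.
Ordinary least squares (statsmodels) provides the estimates, the standard
errors of the regression, and R^2.  An optional diagnostic column counts
terminal m6A-U pairs; the production model omits it because its fitted
value is not significantly different from zero.

The interface follows the statsmodels convention: build a
:class:`StackRegression` model from data, call :meth:`~StackRegression.fit`
to get a :class:`StackFitResult` with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .energy import DuplexSpec
from .params import NNParameterSet, canonical_stack, m6a_stack_contexts


class FitError(ValueError):
    pass


TERMINAL_COLUMN = "terminal_6U"


def _context_label(key: tuple[str, str]) -> str:
    return f"{key[0]}/{key[1]}"


def duplex_stack_walk(params: NNParameterSet, duplex: DuplexSpec):
    """Yield the canonical stack context of each adjacent pair of base
    pairs in a fully helical duplex, plus its terminal pairs."""
    s1, s2, selfc = duplex.resolved(params)
    n = len(s1)
    if len(s2) != n:
        raise FitError("helical duplex strands must have equal length")
    reg = s2[::-1]
    pairs = []
    for i in range(n):
        if not params.alphabet.can_pair(s1[i], reg[i]):
            raise FitError(
                f"unpairable register {s1[i]}-{reg[i]} at position {i + 1} "
                f"of {s1}/{s2}")
        pairs.append(s1[i] + reg[i])
    stacks = [canonical_stack(pairs[i],
                              (pairs[i + 1][1] + pairs[i + 1][0]))
              for i in range(n - 1)]
    return stacks, (pairs[0], pairs[-1][::-1]), selfc


@dataclass(frozen=True)
class StackFitInput:
    """Duplexes with experimental dG37 (from T_M-plot fits), each
    containing at least one m6A-U pair."""

    duplexes: tuple

    def __post_init__(self):
        object.__setattr__(self, "duplexes", tuple(self.duplexes))


def _m6a_alphabet_carrier(m6a_params):
    if m6a_params is not None:
        return m6a_params
    from types import SimpleNamespace

    from .alphabet import m6a_alphabet
    return SimpleNamespace(alphabet=m6a_alphabet())


def build_design_matrix(data: StackFitInput, rna_params: NNParameterSet,
                        m6a_params: NNParameterSet | None = None,
                        include_terminal: bool = False):
    """Counts matrix X over the 15 m6A stack contexts and residual y.

    y_d = dG37_d - (non-m6A stacks + duplex init + terminal A-U penalties
    + symmetry term for self-complementary duplexes).  Duplexes with no
    m6A stack context are rejected.
    """
    contexts = m6a_stack_contexts()
    labels = [_context_label(c) for c in contexts]
    cols = labels + ([TERMINAL_COLUMN] if include_terminal else [])
    m6a_params = _m6a_alphabet_carrier(m6a_params)
    rows, ys, names = [], [], []
    for duplex, dg in data.duplexes:
        if isinstance(duplex, str):
            duplex = DuplexSpec(duplex)
        stacks, (end1, end2), selfc = duplex_stack_walk(m6a_params, duplex)
        counts = dict.fromkeys(cols, 0)
        fixed = rna_params.duplex_init
        if selfc:
            fixed += rna_params.symmetry_corr
        any_m6a = False
        for ctx in stacks:
            if "6" in ctx[0] + ctx[1]:
                any_m6a = True
                counts[_context_label(ctx)] += 1
            else:
                fixed += rna_params.stack[ctx]
        for end in (end1, end2):
            if "6" in end:
                any_m6a = True
                if include_terminal:
                    counts[TERMINAL_COLUMN] += 1
            else:
                fixed += rna_params.terminal_pair_penalty(end)
        if not any_m6a:
            raise FitError(
                f"duplex {duplex.strand1} has no m6A stack context")
        rows.append([counts[c] for c in cols])
        ys.append(dg - fixed)
        names.append(duplex.strand1)
    X = pd.DataFrame(rows, columns=cols, index=names)
    y = pd.Series(ys, index=names, name="residual_dG37")
    return X, y


@dataclass
class StackFitResult:
    """OLS estimates of the m6A-U stack parameters."""

    coefficients: dict
    standard_errors: dict
    r_squared: float
    residuals: pd.Series
    terminal_term: tuple[float, float] | None
    nobs: int

    def summary(self) -> str:
        lines = [
            "m6A-U helix stack parameters (ordinary least squares)",
            f"  duplexes: {self.nobs}   parameters: "
            f"{len(self.coefficients) + (self.terminal_term is not None)}   "
            f"R^2: {self.r_squared:.3f}",
            "  context      dG37    SE   (kcal/mol)",
        ]
        for k in sorted(self.coefficients):
            lines.append(f"  {k:<10} {self.coefficients[k]:7.2f} "
                         f"{self.standard_errors[k]:5.2f}")
        if self.terminal_term is not None:
            v, se = self.terminal_term
            lines.append(f"  {TERMINAL_COLUMN:<10} {v:7.2f} {se:5.2f}")
        return "\n".join(lines)

    def as_fitted_stacks(self) -> dict[tuple[str, str], float]:
        """Coefficients keyed by canonical context, consumable by
        :func:`m6afold.params.build_m6a_tables`."""
        out = {}
        for label, v in self.coefficients.items():
            p1, p2 = label.split("/")
            out[canonical_stack(p1, p2)] = v
        return out


class StackRegression:
    """OLS model for the 15 m6A-U helix stacks.

    Parameters
    ----------
    data:
        :class:`StackFitInput` (or an iterable of ``(DuplexSpec, dG37)``).
    rna_params, m6a_params:
        the unmodified parameter set supplying fixed terms, and any m6A
        set supplying the extended pairing alphabet.
    include_terminal:
        add the diagnostic terminal m6A-U column.
    """

    def __init__(self, data, rna_params: NNParameterSet,
                 m6a_params: NNParameterSet | None = None,
                 include_terminal: bool = False):
        if not isinstance(data, StackFitInput):
            data = StackFitInput(tuple(data))
        self.data = data
        self.rna_params = rna_params
        self.m6a_params = m6a_params
        self.include_terminal = include_terminal
        self.X, self.y = build_design_matrix(
            data, rna_params, m6a_params, include_terminal)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, rna_params, m6a_params=None,
                       include_terminal: bool = False) -> "StackRegression":
        """Build from a table with columns ``strand1``, ``strand2``
        (empty/NaN for self-complementary) and ``dg37``."""
        duplexes = []
        for _, row in df.iterrows():
            s2 = row.get("strand2")
            if s2 is None or (isinstance(s2, float) and np.isnan(s2)) \
                    or s2 == "":
                s2 = None
            duplexes.append((DuplexSpec(row["strand1"], s2),
                             float(row["dg37"])))
        return cls(duplexes, rna_params, m6a_params, include_terminal)

    def fit(self) -> StackFitResult:
        X = self.X
        rank = np.linalg.matrix_rank(X.values)
        if rank < X.shape[1]:
            # report which columns cannot be resolved
            bad = [c for c in X.columns
                   if X[c].sum() == 0
                   or np.linalg.matrix_rank(X.drop(columns=c).values) == rank]
            raise FitError(f"design matrix rank deficient; unresolvable "
                           f"columns: {bad}")
        res = sm.OLS(self.y.values, X.values).fit()
        coeffs = dict(zip(X.columns, res.params))
        ses = dict(zip(X.columns, res.bse))
        terminal = None
        if self.include_terminal:
            terminal = (coeffs.pop(TERMINAL_COLUMN),
                        ses.pop(TERMINAL_COLUMN))
        return StackFitResult(
            coefficients=coeffs, standard_errors=ses,
            r_squared=float(res.rsquared),
            residuals=pd.Series(res.resid, index=X.index),
            terminal_term=terminal, nobs=int(res.nobs))


def methylation_ddg_summary(result: StackFitResult,
                            rna_params: NNParameterSet) -> pd.DataFrame:
    """Per-context and mean destabilization per methylation.

    ddG of a context is the fitted m6A stack minus the analogous all-A
    stack, divided by the number of methylated pairs in the context.
    """
    rows = []
    for label, v in result.coefficients.items():
        p1, p2 = label.split("/")
        analog = rna_params.stack[(p1.replace("6", "A"), p2.replace("6", "A"))]
        nmeth = (p1 + p2).count("6")
        rows.append({"context": label, "dg37": v, "analog_dg37": analog,
                     "n_methyl": nmeth,
                     "ddg_per_methyl": (v - analog) / nmeth})
    df = pd.DataFrame(rows).set_index("context").sort_index()
    df.attrs["mean_ddg_per_methyl"] = float(df["ddg_per_methyl"].mean())
    return df
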