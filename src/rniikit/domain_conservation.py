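"""Per-domain pairwise percent identity and per-column residue profiles.

Percent identity between two aligned rows is computed over their
*co-ungapped* columns only (columns where neither row is a gap); this
denominator is the one least distorted by lineage-specific insertions.
``'X'`` counts as a mismatch even against itself. A pair with zero
co-ungapped columns gets a missing value (NaN). Self-identity is defined
as 100 for any row with at least one non-gap position in the domain.

Consensus profiles give, per alignment column, the frequency of each of
the 20 amino acids among non-gap, non-'X' characters; they back the
signature-string rendering in which an uppercase letter marks a highly
conserved residue, lowercase a commonly occurring one, and 'x' anything
else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .family_io import AA20, GAP, AlignedFamily, FamilyError


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # square, symmetric, percent in [0, 100], NaN = missing
    domain_name: str = ""

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise FamilyError("identity matrix shape does not match ids")

    def reorder(self, ids: list[str]) -> "IdentityMatrix":
        """Reorder rows/columns, e.g. to match a tree-tip ordering."""
        missing = [i for i in ids if i not in set(self.ids)]
        if missing or len(ids) != len(self.ids):
            raise FamilyError(
                f"reorder ids do not match matrix ids (unknown: {missing})"
            )
        idx = [self.ids.index(i) for i in ids]
        return IdentityMatrix(list(ids), self.values[np.ix_(idx, idx)], self.domain_name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for a, id_a in enumerate(self.ids):
            for b, id_b in enumerate(self.ids):
                rows.append((id_a, id_b, self.domain_name, self.values[a, b]))
        return pd.DataFrame(rows, columns=["id_a", "id_b", "domain", "identity"])

    def mean_offdiagonal(self) -> float:
        """Mean identity over distinct pairs, ignoring missing values."""
        n = len(self.ids)
        iu = np.triu_indices(n, k=1)
        return float(np.nanmean(self.values[iu]))


@dataclass
class ConsensusProfile:
    columns: list[int]  # 1-based column indices retained in the profile
    probs: pd.DataFrame  # index = columns, columns = the 20 amino acids

    def __post_init__(self) -> None:
        if list(self.probs.index) != self.columns:
            raise FamilyError("profile index does not match column list")
        sums = self.probs.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise FamilyError("profile rows must each sum to 1")
        if (self.probs.to_numpy() < 0).any():
            raise FamilyError("profile probabilities must be non-negative")

    def to_long(self) -> pd.DataFrame:
        long = self.probs.stack().reset_index()
        long.columns = ["column", "residue", "probability"]
        return long


def _char_matrix(fam: AlignedFamily) -> np.ndarray:
    return np.array([list(fam[i]) for i in fam.ids], dtype="<U1")


def pairwise_identity(fam: AlignedFamily, domain_name: str = "") -> IdentityMatrix:
    """Symmetric percent-identity matrix over co-ungapped columns."""
    mat = _char_matrix(fam)
    non_gap = mat != GAP
    # match requires equality, both non-gap, and not the ambiguity character
    unambiguous = non_gap & (mat != "X")
    n = len(fam.ids)
    values = np.full((n, n), np.nan)
    for a in range(n):
        both = non_gap[a] & non_gap  # (n, L)
        matches = (mat[a] == mat) & both & unambiguous[a][None, :]
        denom = both.sum(axis=1).astype(float)
        num = matches.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            values[a] = np.where(denom > 0, 100.0 * num / denom, np.nan)
    # self-identity is 100 by definition when the row is not all-gap here
    for a in range(n):
        values[a, a] = 100.0 if non_gap[a].any() else np.nan
    return IdentityMatrix(fam.ids, values, domain_name)


def consensus_profile(fam: AlignedFamily, columns: list[int]) -> ConsensusProfile:
    """Per-column amino-acid frequencies with a gap-excluded denominator.

    Columns with no scorable character (all gap or all 'X') are excluded
    from the profile with a warning.
    """
    for c in columns:
        if not 1 <= c <= fam.n_columns:
            raise FamilyError(f"profile column {c} outside 1..{fam.n_columns}")
    mat = _char_matrix(fam)
    kept: list[int] = []
    rows = []
    aa = list(AA20)
    for c in columns:
        chars = mat[:, c - 1]
        scorable = chars[(chars != GAP) & (chars != "X")]
        if scorable.size == 0:
            warnings.warn(
                f"consensus_profile: column {c} has no scorable residues; excluded",
                stacklevel=2,
            )
            continue
        counts = pd.Series(scorable).value_counts()
        rows.append([counts.get(a, 0) / scorable.size for a in aa])
        kept.append(c)
    probs = pd.DataFrame(rows, index=kept, columns=aa, dtype=float)
    return ConsensusProfile(kept, probs)


def signature_string(
    profile: ConsensusProfile,
    major_threshold: float = 0.9,
    minor_threshold: float = 0.5,
) -> str:
    """Render a profile as a consensus signature.

    Per column: uppercase letter if the top residue's frequency reaches
    ``major_threshold``, lowercase if it reaches ``minor_threshold``,
    otherwise ``'x'``. Ties on the top residue break alphabetically.
    """
    if not (0 < minor_threshold <= major_threshold <= 1):
        raise FamilyError("need 0 < minor_threshold <= major_threshold <= 1")
    out = []
    for col in profile.columns:
        row = profile.probs.loc[col]
        top = row.max()
        # alphabetically first among ties for determinism
        residue = sorted(row.index[row == top])[0]
        if top >= major_threshold:
            out.append(residue.upper())
        elif top >= minor_threshold:
            out.append(residue.lower())
        else:
            out.append("x")
    return "".join(out)
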