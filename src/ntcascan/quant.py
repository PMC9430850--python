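"""Quantification formulas used in the nitrogen-response study design.

* Pfaffl efficiency-corrected qPCR expression ratios against a reference
  gene (rnpB-style internal control).
* Hi3 label-free absolute protein amounts: the mean of a protein's three
  most intense unique peptides, scaled by a spiked internal-standard
  protein of known amount (50 fmol phosphorylase B on column is the
  classic setup).
* Beer-Lambert spectrophotometry: phycoerythrin from A542 with the
  hexamer extinction coefficient, and 2-oxoglutarate from the NADPH
  consumed by glutamate dehydrogenase at 340 nm (1:1 stoichiometry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SpectroParams:
    """Spectrophotometric constants.

    pe_epsilon is the molar extinction coefficient of the phycoerythrin
    hexamer at 542 nm (M-1 cm-1).  og_epsilon_nadph is the NADPH molar
    extinction coefficient at 340 nm; 6,220 M-1 cm-1 is the standard
    literature value.  path_length is in cm.
    """

    pe_epsilon: float = 2.15e6
    pe_wavelength: float = 542.0
    og_epsilon_nadph: float = 6220.0
    path_length: float = 1.0

    def __post_init__(self) -> None:
        if min(self.pe_epsilon, self.og_epsilon_nadph, self.path_length) <= 0:
            raise ValueError("spectrophotometric constants must be positive")


def _check_efficiency(e: float, name: str) -> None:
    if not 1 < e <= 2:
        raise ValueError(
            f"{name} amplification efficiency must lie in (1, 2], got {e}"
        )


def pfaffl_ratio(
    target_ctrl_ct: float,
    target_sample_ct: float,
    ref_ctrl_ct: float,
    ref_sample_ct: float,
    e_target: float = 2.0,
    e_ref: float = 2.0,
) -> float:
    """Efficiency-corrected relative expression ratio.

    ratio = E_t^(Ct_ctrl - Ct_sample) / E_ref^(Ct_ctrl - Ct_sample),
    with delta-Ct taken control minus sample so that higher expression
    in the sample gives a ratio above 1.
    """
    _check_efficiency(e_target, "target")
    _check_efficiency(e_ref, "reference")
    return (
        e_target ** (target_ctrl_ct - target_sample_ct)
        / e_ref ** (ref_ctrl_ct - ref_sample_ct)
    )


def signed_fold(ratio: float) -> float:
    """Expression ratio -> the field's signed fold convention.

    A ratio of 0.25 reads -4 (4-fold down); ratios >= 1 are reported
    as-is.
    """
    if ratio <= 0:
        raise ValueError(f"expression ratio must be positive, got {ratio}")
    return ratio if ratio >= 1 else -1.0 / ratio


def ratio_from_signed_fold(fold: float) -> float:
    """Inverse of :func:`signed_fold`."""
    if -1 < fold < 1:
        raise ValueError(f"signed fold {fold} has magnitude < 1")
    return fold if fold >= 1 else -1.0 / fold


@dataclass
class PeptideTable:
    """Per-peptide intensities with a spiked internal standard.

    ``df`` columns: protein_id, peptide_id, intensity, unique (bool).
    """

    df: pd.DataFrame
    standard_id: str
    standard_amount: float = 50.0  # fmol on column

    REQUIRED = ("protein_id", "peptide_id", "intensity", "unique")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"peptide table missing columns: {missing}")
        if (self.df["intensity"] < 0).any():
            raise ValueError("peptide intensities must be >= 0")
        if self.standard_id not in set(self.df["protein_id"]):
            raise ValueError(
                f"internal standard {self.standard_id!r} absent from table"
            )

    @classmethod
    def from_tsv(
        cls, path: str | Path, standard_id: str, standard_amount: float = 50.0
    ) -> "PeptideTable":
        df = pd.read_csv(path, sep=None, engine="python")
        if "unique" in df.columns:
            df["unique"] = df["unique"].astype(bool)
        return cls(df=df, standard_id=standard_id, standard_amount=standard_amount)

    def protein_ids(self) -> list[str]:
        return sorted(set(self.df["protein_id"]))


def _top3_mean(table: PeptideTable, protein_id: str) -> tuple[float, int]:
    sub = table.df[
        (table.df["protein_id"] == protein_id) & table.df["unique"]
    ]
    if len(sub) < 2:
        raise ValueError(
            f"protein {protein_id!r} has {len(sub)} unique peptide(s); "
            "Hi3 quantification needs at least two"
        )
    # ties at rank 3 resolved by peptide id for determinism
    sub = sub.sort_values(
        ["intensity", "peptide_id"], ascending=[False, True]
    ).head(3)
    return float(sub["intensity"].mean()), len(sub)


def hi3_amount(table: PeptideTable, protein_id: str) -> float:
    """Absolute amount (fmol) of one protein by the Hi3 strategy.

    amount = mean(top-3 unique-peptide intensities) /
             mean(top-3 of the internal standard) * standard fmol.
    With exactly two unique peptides the mean of two is used and a
    warning is raised.
    """
    mean_p, n_used = _top3_mean(table, protein_id)
    mean_std, _ = _top3_mean(table, table.standard_id)
    if mean_std <= 0:
        raise ValueError("internal standard has zero total intensity")
    if n_used == 2:
        warnings.warn(
            f"protein {protein_id!r}: Hi3 estimate from only two unique peptides",
            stacklevel=2,
        )
    return mean_p / mean_std * table.standard_amount


def hi3_table(table: PeptideTable) -> pd.DataFrame:
    """Hi3 amounts for every protein with >=2 unique peptides.

    Returns a DataFrame (protein_id, fmol, n_peptides_used); proteins
    below the two-unique-peptide floor are silently excluded.
    """
    rows = []
    mean_std, _ = _top3_mean(table, table.standard_id)
    for pid in table.protein_ids():
        sub = table.df[(table.df["protein_id"] == pid) & table.df["unique"]]
        if len(sub) < 2:
            continue
        mean_p, n_used = _top3_mean(table, pid)
        rows.append((pid, mean_p / mean_std * table.standard_amount, n_used))
    return pd.DataFrame(rows, columns=["protein_id", "fmol", "n_peptides_used"])


def normalize_total_abundance(amounts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so per-sample totals equal the mean total.

    ``amounts`` is proteins x samples (fmol).  Total-abundance
    normalization corrects for loading differences — here standing in
    for a "normalize to all proteins" style correction.
    """
    totals = amounts.sum(axis=0)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"sample(s) with zero total abundance: {zero}")
    return amounts * (totals.mean() / totals)


def pe_concentration(
    a542: float, params: SpectroParams = SpectroParams()
) -> float:
    """Phycoerythrin hexamer concentration (M) from absorbance at 542 nm."""
    if a542 < 0:
        raise ValueError(f"absorbance must be >= 0, got {a542}")
    return a542 / (params.pe_epsilon * params.path_length)


def og_amount(
    delta_a340: float,
    reaction_volume_l: float,
    protein_mg: float,
    params: SpectroParams = SpectroParams(),
) -> float:
    """2-oxoglutarate (nmol per mg protein) from NADPH oxidation at 340 nm.

    The glutamate-dehydrogenase assay consumes one NADPH per 2-OG, so
    nmol 2-OG = delta-A340 / (eps * l) * V * 1e9, normalized to the
    protein content of the extract.
    """
    if delta_a340 < 0:
        raise ValueError("delta A340 is the magnitude of the decrease (>= 0)")
    if protein_mg <= 0:
        raise ValueError(f"protein amount must be positive, got {protein_mg}")
    nmol = (
        delta_a340
        / (params.og_epsilon_nadph * params.path_length)
        * reaction_volume_l
        * 1e9
    )
    return nmol / protein_mg


def welch_p(a, b) -> float:
    """Two-sided Welch t-test p-value (routine replicate-comparison utility)."""
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def pfaffl_from_table(
    ct: pd.DataFrame,
    ref_gene: str,
    control_condition: str = "control",
) -> pd.DataFrame:
    """Per-gene Pfaffl ratios from a replicate Ct table.

    ``ct`` columns: gene, condition, replicate, ct, efficiency.  Ct
    values are averaged over replicates per (gene, condition); every
    non-control condition is compared against ``control_condition``
    using ``ref_gene`` as the internal control.  Returns (gene,
    condition, ratio, signed_fold).
    """
    for col in ("gene", "condition", "ct", "efficiency"):
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    if ref_gene not in set(ct["gene"]):
        raise ValueError(f"reference gene {ref_gene!r} absent from Ct table")
    mean_ct = ct.groupby(["gene", "condition"])["ct"].mean()
    eff = ct.groupby("gene")["efficiency"].mean()
    conditions = [c for c in ct["condition"].unique() if c != control_condition]
    rows = []
    for gene in sorted(set(ct["gene"]) - {ref_gene}):
        for cond in conditions:
            r = pfaffl_ratio(
                target_ctrl_ct=mean_ct[(gene, control_condition)],
                target_sample_ct=mean_ct[(gene, cond)],
                ref_ctrl_ct=mean_ct[(ref_gene, control_condition)],
                ref_sample_ct=mean_ct[(ref_gene, cond)],
                e_target=float(eff[gene]),
                e_ref=float(eff[ref_gene]),
            )
            rows.append((gene, cond, r, signed_fold(r)))
    return pd.DataFrame(rows, columns=["gene", "condition", "ratio", "signed_fold"])
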