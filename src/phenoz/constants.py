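"""Shared numerical constants of the harmonization pipeline."""

#: Cap on |z| (raw and adjusted).  Two-sided p-values below ~1e-15 underflow
#: through the normal quantile; clamping keeps the effect matrix finite.
Z_CAP: float = 8.0

#: Bootstrap target sample size per condition cell: every experiment is
#: resampled to this common n so that Z statistics from assays with very
#: different replication are comparable.
N_BOOT_SIZE: int = 15

#: Default number of bootstrap replicates per cell.
B_DEFAULT: int = 200

#: |adjusted Z| cutpoints for the significance tiers, in increasing order of
#: stringency.  These are the rounded guideline values used to colour the
#: integrated heatmaps: |Z| > 1.67 ~ FDR < 10%, |Z| > 2 ~ FDR < 5%,
#: |Z| > 2.6 ~ FDR < 1%.
TIER_CUTPOINTS: dict[str, float] = {"fdr10": 1.67, "fdr5": 2.0, "fdr1": 2.6}

#: Tier labels from least to most significant.
TIER_ORDER: tuple[str, ...] = ("ns", "fdr10", "fdr5", "fdr1")

#: Token written for not-measured cells in matrix TSVs.
NA_TOKEN: str = "NA"
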