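#!/usr/bin/env python
"""Re-derive headline bookkeeping from the packaged published summary tables.

Runs the cohort arithmetic (pooled % female and the sex-by-survey Pearson
chi-square), counts the distinct novel result groups, and detects the
pleiotropic SNPs and generalized groups from the published pleiotropy
table.  Writes the derived tables under results/published/.
"""

from pathlib import Path

from survey_phewas import published
from survey_phewas.classify import (
    assess_generalization,
    classify_results,
    detect_pleiotropy,
    pleiotropy_to_frame,
    summarize_categories,
)
from survey_phewas.harmonize import summarize_cohort_from_counts

OUT = Path(__file__).resolve().parent.parent / "results" / "published"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = published.load_cohort()
    s = summarize_cohort_from_counts(
        {r.survey: (r.n, r.pct_female) for r in cohort.itertuples(index=False)}
    )
    print(f"pooled % female = {s['pooled_pct_female']:.2f} over n = {s['pooled_n']}")
    print(f"sex-by-survey chi-square = {s['sex_by_survey_chi2']:.2f} "
          f"(p = {s['sex_by_survey_chi2_p']:.2g}, df = {s['sex_by_survey_df']})")

    catalog = published.load_catalog()
    novel = classify_results(published.groups_to_results(published.load_novel_groups()), catalog)
    print(f"novel result groups: {summarize_categories(novel)['novel']}")

    pleio_groups = published.load_pleiotropy_groups()
    classified = classify_results(published.groups_to_results(pleio_groups), catalog)
    records = detect_pleiotropy(classified)
    pleiotropy_to_frame(records).to_csv(OUT / "pleiotropic_snps.tsv", sep="\t", index=False)
    gen = assess_generalization(classified)
    gen.to_csv(OUT / "generalized_groups.tsv", sep="\t", index=False)
    print(f"pleiotropic SNPs in the published table: {len(records)}")
    print(f"generalized (same-sign multi-stratum) groups among them: "
          f"{int((gen['status'] == 'generalized').sum())}")


if __name__ == "__main__":
    main()
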