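# faers-dispro

Disproportionality analysis of spontaneous adverse-drug-event reports in the
FAERS quarterly ASCII format, built around the post-marketing safety profile
of the oral XPO1 inhibitor selinexor (XPOVIO), and reusable for any drug.

Spontaneous-reporting databases such as the FDA Adverse Event Reporting
System (FAERS) have no denominator of exposed patients, so drug–event
associations are screened by *disproportionality*: for each MedDRA Preferred
Term (PT), the event counts are collapsed into a 2×2 table

|              | target PT | other PTs |
|--------------|-----------|-----------|
| target drug  | a         | b         |
| other drugs  | c         | d         |

and two classical measures are computed:

- **Reporting odds ratio** ROR = ad/bc, with the Woolf 95% CI
  exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d));
- **Proportional reporting ratio** PRR = [a/(a+b)] / [c/(c+d)], with the
  uncorrected Pearson χ² = (ad−bc)²(a+b+c+d) / [(a+b)(c+d)(a+c)(b+d)].

A PT is flagged as a signal when **a ≥ 3 and the ROR CI lower bound > 1**,
or **a ≥ 3, PRR > 2 and χ² > 4**. Flags are screening hypotheses for
clinical review, not causal findings; no multiple-testing adjustment is
applied, and every run says so in its log.

The package covers the full workflow:

- `faers_io` — schema-validated parsing/writing of the seven dollar-delimited
  quarterly tables (DEMO, DRUG, REAC, OUTC, INDI, THER, RPSR) and of a
  user-supplied PT→SOC mapping (MedDRA is licensed and not bundled);
- `dedup_cohort` — the FDA deduplication rule (per case keep the largest
  FDA_DT, ties to the largest PRIMARY_ID), primary-suspect cohort selection
  by drug-name substring search, and the distinct (report, PT) event list;
- `descriptives` — annual report counts, demographics with explicit N/A rows,
  severe-outcome distribution, top-N PT and SOC frequency tables, PT groups;
- `disproportionality` — ROR/PRR/χ², thresholds, ranking, TSV export;
- `synthetic_data` — a seeded generator of FAERS-like multi-table datasets
  with planted drug–event signals of chosen strength, plus the analytic
  expected 2×2 cells for consistency checks;
- `cli_report` — the `faers-dispro` command-line tool.

## Worked example

Simulate 5,000 cases (two PTs planted at rate ratio 10 for the target drug)
and run the full pipeline:

```bash
faers-dispro simulate --out-dir demo/data --n-cases 5000 --seed 7
faers-dispro full --input-dir demo/data --output-dir demo/out
```

The run log audits every stage:

```
parse: DEMO -> 6059 records, 0 skipped lines
dedup: 6059 report versions -> 5000 cases (1059 removed)
cohort: 246 target reports, 992 target events, 19040 background events, ...
disproportionality: 78 PTs evaluated, 3 flagged as signals
```

6,059 DEMO rows collapse to 5,000 cases (the extra 1,059 are duplicate report
versions removed by the FDA rule); 246 deduplicated reports name the target
drug as primary suspect. `demo/out/signals_top.tsv` then contains:

```
PT                  a    b    c    d      ROR      ROR_CI_low  ROR_CI_high  PRR      chi2
Hypercreatinaemia   55   937  160  18880  6.92636  5.06335     9.47485      6.59778  196.501
Thrombocytopenia    156  836  694  18346  4.93288  4.09158     5.94716      4.3144   338.676
...
```

Both planted PTs are recovered at the top of the ranking with CI lower
bounds far above 1. (Their RORs sit below the planted rate ratio of 10
because neither PT is rare in the background; the odds-ratio implied by the
generator — `expected_ror(config, pt)` — is the right comparison point, not
the raw rate ratio.) Descriptive tables land next to the signals, e.g.
`table_gender.tsv`:

```
category  n    percent
Male      43   17.5
Female    30   12.2
N/A       173  70.3
```

with the N/A-dominated pattern typical of consumer-filed spontaneous reports.

To analyse a real FAERS extract instead, point `--input-dir` at a directory
containing the seven ASCII tables named `DEMO.txt` … `RPSR.txt`, pass your
drug search strings via repeated `--drug-name` flags, and supply a
two-column PT→SOC TSV via `--pt-soc-map` for the SOC table.

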