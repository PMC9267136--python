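# splicework

Functional characterization of putative spliceogenic variants from RNA-seq
splice-junction evidence, for clinical variant curation.

Most variants outside the canonical GT-AG dinucleotides that are *predicted*
to disturb splicing sit in the variant-of-uncertain-significance (VUS) tier
until an RNA assay settles the question. `splicework` implements the
downstream half of that assay as a reusable, tested pipeline:

1. **Triage** — decide which VUS qualify for RNA analysis from a panel of
   splice-site predictor scores (SpliceAI Δ gate plus NNSplice / MaxEntScan /
   GeneSplicer / SSF rules).
2. **Event detection and nomenclature** — interpret non-canonical junctions
   from STAR `SJ.out.tab` tables against a transcript model: whole/partial
   exon skipping (Δn, Δnp, Δnq), pseudoexon inclusion (▼n) and partial
   intron retention (▼np, ▼nq), each with an HGVS-style r. description and
   its reading-frame consequence.
3. **Quantification** — per-junction expression of each aberrant event,
   `100·a/(a+n)` for `a` aberrant vs `n` canonical junction reads, compared
   against a control cohort; allele-resolved full-length fractions where an
   exonic tag SNP is available.
4. **Splicing-impact class** — 1S (no effect), 2S (partial or uncertain),
   3S (complete: the variant allele yields no full-length transcript).
5. **ACMG/AMP combination** — evidence strings with splicing-specific
   strengths (PS3 strong only for 3S, PS3-m when completeness is
   undecidable, BS3-SA as stand-alone benign for silent/intronic variants
   with disproven predictions) combined into the five-tier classification
   (1-B … 5-P).

A synthetic-data module draws carrier and control samples as transcript-
species observations (junction tables + allele-tagged read records) with
configurable event fractions, NMD attenuation, depth and background levels,
so the whole pipeline is testable without patient data. A bundled reference
cohort of 12 characterized variants in APC, ATM, FH, LZTR1, MSH6, PALB2,
RAD51C and TP53 serves as the standing fixture.

## Worked example

A carrier of a donor-site variant whose allele produces two aberrant
species (36% cryptic-donor deletion, 2% exon skip) and no full-length
transcript:

```python
from splicework.cohort import cohort_models
from splicework.events import event_from_r
from splicework.simulate import SimulationSpec, simulate_sample, simulate_control_cohort
from splicework.junctions import (detect_aberrant, quantify_event,
                                  compare_to_controls, allele_fulllength_fraction,
                                  EventQuantification)
from splicework.classify import SplicingResult, classify_splicing
from splicework import acmg

model = cohort_models()["LZTR1"]
spec = SimulationSpec(
    model=model,
    events=[(event_from_r("r.1831_1942del", model), 0.36),
            (event_from_r("r.1786_1942del", model), 0.02)],
    alt_fulllength_fraction=0.0,   # variant allele yields no full-length mRNA
    depth=20_000, seed=42,
)
carrier = simulate_sample(spec)
controls = simulate_control_cohort(spec, n_controls=5)

quants = []
for ev in detect_aberrant(carrier.table, model):
    pct = quantify_event(ev, carrier.table, model)
    ctrl = [quantify_event(ev, t, model) if t.counts else 0.0 for t in controls]
    associated, _ = compare_to_controls(pct, ctrl)
    quants.append(EventQuantification(ev, pct, ctrl, variant_associated=associated))
    print(f"{ev.symbol:5s} {ev.kind.value:25s} {pct:5.2f}% carrier, "
          f"{sum(ctrl)/5:.2f}% controls, associated={associated}")

split = allele_fulllength_fraction(carrier.reads, model)
print(f"full-length alt {split['alt']:.2f}% / ref {split['ref']:.2f}%")

result = SplicingResult("LZTR1:c.1942G>T", quants, tag_available=True,
                        alt_fulllength_percent=split["alt"])
print("splicing class:", classify_splicing(result))
print("ACMG class:", acmg.parse_evidence("PM2, PP3, PS3, PP4").combined_class)
```

prints

```
Δ16   exon-skip                  2.39% carrier, 0.00% controls, associated=True
Δ16q  partial-exon-del-donor    36.08% carrier, 0.00% controls, associated=True
full-length alt 0.00% / ref 62.66%
splicing class: 3S
ACMG class: 4-LP
```

The two detected events recover their simulated fractions (the 36% event
reads slightly above 36 because the per-junction ratio competes each event
only against reads using the canonical junction it replaces), the tag SNP
shows zero full-length output from the variant allele — a complete splicing
defect (3S) — and PS3 at full strength combines with PM2/PP3/PP4 to a
likely-pathogenic call.

## Command line

```sh
splicework characterize --config run.yaml --out report.tsv --log run.log
splicework simulate --spec sim.yaml --out-dir simdata/
splicework classify-evidence --in evidence.tsv --out classes.tsv
splicework triage --in scores.tsv --out selected.tsv
```

`characterize` emits one row per variant (variant type DI/DE/3'ss/5'ss,
event symbols, r. descriptions, frame effects, carrier/control percentages,
splicing class, evidence, final class) and a structured log of every
threshold decision.

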