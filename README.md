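# equiframe

Rubric-based content analysis of health policy documents against the
EquiFrame framework: 21 **core concepts** of human rights (Access,
Non-discrimination, Autonomy, Participation, ...) crossed with 12
**vulnerable groups** (persons with disabilities, the aged, youth, displaced
populations, ...) plus a distinguished **Universal** column for statements
addressing the total population ("all people", "everyone").

It is written for health-policy researchers who appraise "policy on the
books": the toolkit proposes key-language mention candidates for human
raters, aggregates rater judgments into a score matrix, computes the summary
indices used to benchmark policies within and across countries, quantifies
dual-rater reliability, and generates synthetic policy corpora with planted
ground truth so the whole pipeline is testable without redistributable
policy texts.

## The scoring model

Each reference to a core concept is rated on a 1–4 quality scale:

| score | meaning |
|---|---|
| 1 | concept only mentioned |
| 2 | concept mentioned and explained |
| 3 | specific policy actions identified to address the concept |
| 4 | intention to monitor the concept expressed |

A concept irrelevant to the document context is *not applicable* (whole
row).  Mentions are anchored to the vulnerable group named in the same
sentence, or to Universal when only the total population is addressed.  When
a cell receives several references, the top score is kept (the *max rule*).
From the resulting concept × (group + Universal) matrix, three indices are
computed for a document:

- **Core concept coverage** = 100 · (concepts mentioned) / 21
- **Vulnerable group coverage** = 100 · (base groups mentioned) / 12
  (Universal and country-specific extra groups are excluded)
- **Core concept quality** = 100 · (concepts with best score ≥ 3) / 21

and the **overall summary ranking**: *High* if all three indices are ≥ 50%,
*Moderate* if exactly two are, *Low* otherwise.  Thresholds are applied to
full-precision values; display rounding is half-up at a configurable
precision.

## Worked example

```python
import equiframe as ef

fw = ef.default_framework()           # 21 concepts, 12 groups, editable YAML
text = (
    "The ministry shall remove barriers to access for persons with disabilities, "
    "and progress will be monitored annually. Informed consent applies to everyone. "
    "Maternal mortality reduction targets are explained in section four."
)
doc = ef.PolicyDocument(doc_id="demo", text=text, doc_type="policy")

for c in ef.detect_mentions(doc, fw):
    print(f"{c.sentence_index}  {c.category:9s} {c.target_id:22s} '{c.matched_phrase}'")
```

```
0  concept   access                 'barriers to access'
0  group     disabled               'persons with disabilities'
1  concept   autonomy               'informed consent'
1  universal universal              'everyone'
2  group     mother_child_mortality 'maternal mortality'
```

Detection proposes; raters confirm and assign quality.  Sentence 0 states an
action and a monitoring intention for Access toward the Disabled group
(quality 4); sentence 1 merely mentions Autonomy universally (quality 1):

```python
annots = [
    ef.Annotation("r1", "demo", "access", "disabled", 4, evidence=doc.sentences[0].text),
    ef.Annotation("r1", "demo", "autonomy", ef.UNIVERSAL, 1, evidence=doc.sentences[1].text),
]
s = ef.summarize_policy(ef.build_matrix(annots, fw))
vg, cc, q = s.rounded()
print(f"VG {vg}%  CC {cc}%  quality {q}%  -> {s.ranking}  counts={s.counts}")
```

```
VG 8.3%  CC 9.5%  quality 4.8%  -> Low  counts=(2, 1, 1)
```

Two of 21 concepts are mentioned (9.5%), one of 12 groups (8.3%), one
concept reaches quality ≥ 3 (4.8%); no index reaches 50%, so the policy
ranks *Low*.  Note the sentence-2 group mention contributes nothing: a group
named without any concept in reach does not create a matrix cell.

## Command line

`equiframe` exposes the same workflow as subcommands — `detect` (text →
rater worksheet), `score` (annotation CSV → matrix + summary), `compare` and
`consensus` (dual-rater reliability and adjudication), `benchmark` (index
rows → ranked country tables with High/Moderate/Low tallies), and `generate`
(seeded synthetic corpus with ground truth).  Every run writes a JSON run
log with the framework hash and options.  `equiframe benchmark --published`
reproduces the benchmark tables for the 51-policy four-country reference
dataset shipped with the package.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the pipeline from scratch: it generates a seeded synthetic corpus,
recovers every document's planted summary through detection → scoring →
indices, and re-derives the ranking rule and the per-country tallies on the
shipped 51-row reference dataset, printing what it verified.
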