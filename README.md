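# codonopt

Multiparameter codon and mRNA optimization of coding sequences for
recombinant protein expression, built around a deterministic
sliding-window search over synonymous-codon space.

Even in autologous hosts (human genes in human cells), transgene
expression is frequently limited by gene-intrinsic features: rare codons,
AT-rich destabilizing elements, UpA dinucleotides, cryptic splice sites,
intragenic poly(A) signals, repeats and stable RNA secondary structure.
`codonopt` rewrites a coding sequence synonymously — the protein is
untouched — to remove such features while driving codon usage towards the
host optimum, and provides the analysis metrics used to characterize
wildtype/optimized construct panels, plus tools for designing siRNA
rescue experiments that exploit the silent-mutation divergence of
optimized transgenes.

## The model

**Relative adaptiveness** of codon *c* encoding amino acid *a*, given a
reference usage table *f*:

    w(c) = f(c) / max_{c' syn a} f(c')

so the most frequent synonymous codon has w = 1. The **codon adaptation
index** of an ORF with codons c₁…c_L (terminal stop excluded) is the
geometric mean

    CAI = (∏ᵢ w(cᵢ))^(1/L)

with a floor of 0.01 substituted for unused codons.

**Sliding-window optimization.** A variation window of *k* codons
(default 5) moves 5'→3' along the ORF. At each position every combination
of synonymous codons inside the window is enumerated; each candidate
(fixed prefix + window) is scored with a weighted quality function

    S = w_usage·⟨w⟩ − w_gc·|GC − GC*| + w_CpG·nCpG − w_UpA·nUpA
        − Σ motif/splice/repeat/hairpin penalties

evaluated on a bounded look-back context (last 60 nt of the prefix plus
the window). The best candidate's first codon is committed and the window
shifts one codon; the codon-usage term is doubled over the first 15
codons so poor codons are avoided most strictly near the 5' end.
Candidates introducing a new hard-constraint motif (by default the
poly(A) signals AATAAA/ATTAAA) are rejected outright; when the amino-acid
sequence forces the motif in every encoding, the result is flagged
instead. Ties break lexicographically, so the search is fully
deterministic.

## Worked example

```python
from codonopt import (load_human_table, generate_fixture_orf, optimize,
                      sirna_divergence, SirnaQuery)

table = load_human_table()
wt = generate_fixture_orf(60, table, gc_bias=-0.8, seed=11)   # AT-rich "wildtype"
res = optimize(wt, table)

b, a, c = res.report_before, res.report_after, res.comparison
print(f"before: CAI={b.cai:.3f} GC={b.gc_percent:.1f}% CpG={b.cpg_count} UpA={b.upa_count}")
print(f"after : CAI={a.cai:.3f} GC={a.gc_percent:.1f}% CpG={a.cpg_count} UpA={a.upa_count}")
print(f"codons altered: {c.codons_altered_n}/60 ({c.codons_altered_percent}%)")

guide = SirnaQuery(wt.nt[60:81])           # an siRNA hitting the wildtype
print(sirna_divergence(wt, res.output, guide))
```

prints

```
before: CAI=0.695 GC=37.8% CpG=2 UpA=16
after : CAI=0.984 GC=58.3% CpG=5 UpA=7
codons altered: 40/60 (67%)
RescueVerdict(best_wt=(60, 0), best_opt=(60, 4), rescue_compatible=True)
```

The optimized ORF encodes the same protein, its CAI rises from 0.70 to
0.98 and its GC content from 38% to 58% — inside the 0.96–0.99 and
55–67% bands reported for optimized human construct panels — while UpA
dinucleotides drop and CpGs rise. The siRNA that matches the wildtype
perfectly faces 4 mismatches in the optimized copy, so the optimized
transgene can rescue a knockdown of the wildtype.

A bundled reference panel of 50 published human wildtype/optimized
construct metrics (`load_reference_panel()`) supports consistency checks
and expression-ratio statistics (`summarize_ratios`), including the
convention that pairs with no detectable wildtype expression enter the
median at ratio 2.

## Command line

```
codonopt fixtures -n 5 --aa-length 100 --gc-bias -0.8 -o panel.fasta
codonopt optimize panel.fasta --out-fasta panel_opt.fasta --report report.json
codonopt analyze paired.fasta -o table.tsv          # length, CAI, GC%, codons altered
codonopt scan panel.fasta                           # motifs/splice/repeats/hairpins, BED-like
codonopt rescue-check --wt wt.fasta --opt opt.fasta --guide AAGCGTTGAAATAGCGTACAA
codonopt rescue-sites --wt wt.fasta --opt opt.fasta -k 21
```

## Layout

- `codonopt.codon_model` — usage tables, relative adaptiveness, CAI, optimal back-translation
- `codonopt.seq_metrics` — GC, windowed GC, CpG/UpA, codons-altered comparison
- `codonopt.feature_scan` — IUPAC motifs, splice-site consensus models, repeats, hairpins
- `codonopt.optimizer` — quality function, sliding-window and brute-force search
- `codonopt.rnai_tools` — siRNA divergence and rescue-site enumeration
- `codonopt.io_report` — FASTA I/O, pairing, reports, ratio summaries, fixture generation

See `docs/methods.md` for model details, default parameters and known
limitations.
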