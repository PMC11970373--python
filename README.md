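# k9diff

Differential analysis of broad H3K9me3 heterochromatin domains from
binned ChIP-seq signal, with a shuffle-based repeat-enrichment statistic.

H3K9me3 marks constitutive heterochromatin and silences repetitive
elements (LTR/ERV retroelements, SINEs such as Alu and MIR) as well as
genes. When chromatin state shifts between two cell states — for example
between drug-sensitive and drug-resistant cancer cells, or after
knockdown of a chromatin regulator — some H3K9me3 domains are gained,
some are lost, and most are unchanged. `k9diff` implements the complete
desk-side analysis for such experiments:

1. **Signal preparation** — IP and input samples, binned at 200 bp, are
   quantile-normalized (each group separately: the value at genome-wide
   rank *r* becomes the cross-sample mean of rank-*r* values), and noise
   is reduced by subtracting input from IP bin-wise.
2. **Broad-peak calling** — two-cutoff scheme: maximal bin runs with
   signal ≥ the *peak* cutoff form strong cores (e.g. 1000 or 850);
   runs ≥ the lower *linking* cutoff (500 / 425) extend and join them
   across gaps up to `max_link_gap`. A broad peak is a linked weak
   segment containing at least one strong core.
3. **Union and clustering** — per-sample peaks are concatenated, sorted,
   merged and given consecutive cluster ids; each union region
   contributes a 10-kb / 50-bin signal row per condition, the
   concatenated rows are k-means clustered (seeded k-means++), and each
   cluster is labelled **gain**, **loss** or **common** by the
   pseudocounted fold change (mB+1)/(mA+1) between condition means
   against a 1.5× threshold.
4. **Annotation and enrichment** — regions are intersected with
   promoters (TSS ± 1 kb, strand-aware, deduplicated) and a
   RepeatMasker-style catalogue. For each repeat class or subfamily the
   number of regions touching the class (*observed*, O) is compared with
   the same count for each of three length-preserving uniform shuffles
   of the regions (*expected*, E_i):

   ratio_i = O / E_i,   t = (mean(ratio) − 1) / (sd(ratio)/√n),

   tested one-sided against a null mean of 1 with df = n − 1 (n = 3
   shuffles by default). Obs/Exp > 1 indicates the regions sit on that
   repeat class more often than chance.
5. **Synthetic data** — a generator plants exactly this structure
   (Poisson IP/input bin counts, common/gain/loss domains, a repeat
   catalogue with human-like densities, and differential domains
   anchored to a target class with probability `p_enrich`) together with
   a truth table, so every stage is testable without external downloads.

## Worked example

```bash
python examples/03_repeat_enrichment.py
```

prints, for the default planted dataset (seed 7; 40 differential domains
anchored to LTR elements with probability 0.8):

```
40 differential regions vs 2795 repeat elements
class       obs   mean     sd       t        p
LTR          29   3.07   0.94    3.81   0.0313 *
NEUTRAL       7   0.74   0.12   -3.68   0.9668
SINE         24   0.88   0.05   -4.30   0.9750
Satellite     0   flagged: expected-zero
```

Reading: 29 of the 40 differential regions touch an LTR element, about
3.1× more than in the shuffled null, and the one-sided t-test on the
three Obs/Exp ratios rejects the null mean of 1 (p = 0.031). The neutral
control class and SINEs sit at or below chance, and the Satellite class
(no overlaps in any shuffle) is flagged rather than divided by zero.

The other examples cover peak calling (`01`), gain/loss/common
clustering (`02`, which recovers the planted 30/20/20 partition exactly)
and the end-to-end file-based pipeline (`04`). A thin CLI mirrors the
stages (`k9diff simulate|normalize|subtract|callpeaks|union|promoters|`
`annotate|enrich|composition|run`).

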