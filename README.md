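# mutread

Mutational signatures — the characteristic distributions of single-base
substitutions over their trinucleotide contexts that mutational processes
leave in a tumor genome — are usually estimated from whole-genome
sequencing, which is too expensive for large cohorts and often impossible
for degraded clinical (FFPE) material. A cheaper route is *reduced
representation* sequencing: digest the genome with two restriction enzymes,
size-select fragments into a narrow window, and sequence only that
reproducible subset of the genome deeply. Because the recovered mutations
are an approximately random subset of all somatic SNVs, a few hundred of
them suffice to refit the signature profile.

`mutread` implements the computational machinery of such a protocol:

* **digestion** — in-silico double digestion of a genome with an enzyme
  pair (IUPAC-aware site matching, e.g. ApoI `R^AATTY`), fragment
  construction between adjacent cut points, and inclusive size selection
  (default 350–450 bp, mixed-end fragments only), for choosing the enzyme
  combination before any wet-lab work;
* **spectrum** — 96-channel trinucleotide spectra from SNV sets
  (pyrimidine-strand convention, COSMIC channel order), optionally
  restricted to the retained fragments;
* **signatures** — exposure refitting by non-negative least squares
  (NNLS) against a given signature matrix, and cosine-similarity
  comparison of profiles;
* **screening** — the two design experiments: profile stability under
  random mutation subsets of increasing size, and ranking of enzyme
  combinations by how faithfully their reduced representation reproduces
  the full-genome profile;
* **readprep** — preprocessing of the library's paired reads
  (`[UMI][inner barcode][residual restriction tag][insert]`): exact-match
  UMI clone filtering, inner-barcode demultiplexing, RAD-tag verification
  and sliding-window quality filtering;
* **variant_filter** — the post-calling somatic-variant rejection ledger
  (control-allele, mapping-quality, base-quality and strand-bias rules plus
  per-cohort read-support, VAF and control-depth thresholds);
* **synthdata** — generators for genomes with planted restriction sites,
  SNV sets drawn from known signature-exposure mixtures, and library reads
  with controlled duplication, each with an exact truth table.

## The model

A sample's spectrum is a count vector $m \in \mathbb{N}^{96}$ over the six
pyrimidine substitutions (C>A, C>G, C>T, T>A, T>C, T>G) × 16 flanking-base
contexts. Given a signature matrix $S \in \mathbb{R}^{k \times 96}$ (rows
are probability distributions), exposures are

$$\hat x = \arg\min_{x \ge 0} \lVert S^\top x - p \rVert_2, \qquad
p = m / \lVert m \rVert_1,$$

rescaled to sum to one. Profiles $P, Q$ are compared by cosine similarity
$\mathrm{cossim}(P,Q) = \sum_i P_i Q_i \,/\, (\lVert P\rVert_2 \lVert
Q\rVert_2)$, which is 1 for identical and 0 for disjoint-support profiles.

## Worked example

Generate a 60 kb genome with two PstI/ApoI fragment pairs planted, draw
2000 SNVs from a known three-signature mixture (0.5/0.3/0.2), digest,
and compare the reduced-representation profile with the full one:

```sh
mutread synth genome --length 60000 \
    --sites "PstI:2000,ApoI:2400,PstI:9000,ApoI:9380" --seed 3 --out genome.fa
mutread synth mutations --fasta genome.fa \
    --exposures "0.5,0.3,0.2,0,0,0" --n 2000 --seed 4 --out sample.vcf
mutread digest --fasta genome.fa --enzyme-a PstI --enzyme-b ApoI --out frags.bed
mutread spectrum --vcf sample.vcf --fasta genome.fa --out spec.tsv
mutread fit --spectrum spec.tsv --signatures sigs.tsv --out expo.tsv
```

(`sigs.tsv` here is the packaged synthetic six-signature set, written with
`mutread.synthdata.synthetic_signature_matrix().to_tsv("sigs.tsv")`.)
This prints:

```
wrote genome.fa with 4 planted sites
wrote 2000 SNVs to sample.vcf
2 fragments retained, 772 bp covered
2000 SNVs counted, 0 skipped
residual 0.02284 on 2000 mutations
```

and `expo.tsv` holds the refitted exposures — the planted mixture is
recovered from the multinomially sampled mutations:

```
signature	weight
SynthSig1	0.5074197957
SynthSig2	0.2938913691
SynthSig3	0.1939147604
...
```

Restricting the spectrum to the 772 bp of retained fragments keeps only 28
of the 2000 mutations, yet the refitted profile still tracks the
full-genome one closely:

```sh
mutread spectrum --vcf sample.vcf --fasta genome.fa --regions frags.bed --out spec_rr.tsv
mutread fit --spectrum spec_rr.tsv --signatures sigs.tsv --out expo_rr.tsv
mutread cossim expo.tsv expo_rr.tsv
# 0.982547
```

That cosine — reduced representation versus full profile — is the
quantity the enzyme-screen experiment (`mutread screen`) maximises over
candidate enzyme pairs.

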