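# bmctyper

Identification and typing of **bacterial microcompartment (BMC) loci** in
protein sequence data with profile HMMs.

BMCs are protein organelles: a shell of pfam00936 hexamers (BMC-H, the
permuted BMC-H^p, tandem-domain BMC-T^s/T^sp/T^dp trimers) capped by
pfam03319 pentamers (BMC-P), encapsulating a metabolic core (signature
enzyme, AldDh, AlcDh, PTAC).  Their genes cluster in operon-like loci
whose component inventory and gene order are characteristic of functional
BMC types (carboxysomes, EUT, PDU, GRM, SPU, ...).  bmctyper is for
microbial genomicists and metagenomicists who want to ask, for a proteome
or candidate locus: *does this organism carry a BMC, and of which type?*

## What it computes

1. **Profile HMM search** — per-family position-specific models built from
   training alignments (match states = columns with gap fraction ≤ 0.5,
   +1/20 emission pseudocounts) or imported from HMMER3/f ASCII files.
   Scoring is built in: a forward-algorithm log-odds bitscore over a
   multihit local Plan7-style topology,
   `bits = log2(P_fwd(seq|profile) / P(seq|background))`, with hits
   accepted at ≥ 20 bits by default.
2. **Best-hit annotation** — one profile per protein (max bitscore, ties
   lexicographic), mapped to roles and the standard display colors
   (yellow BMC-P, blue BMC-H/H^p, light blue BMC-T^s/T^sp, teal BMC-T^dp,
   purple signature enzyme, orange regulator, red AldDh, green AlcDh,
   magenta PTAC, black other conserved, grey unassigned).
3. **Locus fingerprints and similarity** — the ordered best-hit labels of
   a locus, compared as `S = ½·Jaccard(inventory) + ½·order`, where order
   is the best label-match fraction over all offsets and both strand
   orientations.  The five closest reference types are reported; loci can
   be clustered single-linkage at S ≥ 0.6.
4. **Type call** — majority vote over the BMC types of the typed matches:
   a unique mode with ≥ 50% of votes is *assigned* (confidence =
   modal/total); otherwise *ambiguous* (with signature-enzyme types listed
   as a hint); no shell match at all is *no_shell*.
5. **Proteome mode** — shell-profile-only scan with a per-class summary,
   expanding hits to ±12-gene candidate loci (overlapping/touching windows
   merge).
6. **Reports** — assignment TSVs, SVG/HTML locus diagrams (bar length ∝
   protein length, green/red labels for agreement with the called type),
   SWISS-MODEL submission links, and a 68-type reference registry.

## Worked example

Generate a small synthetic world (3 BMC types, 2 loci each) and type one
of its loci:

```sh
bmctyper simulate --seed 42 --n-types 3 --loci-per-type 2 --locus-len 12 \
    --out world
bmctyper call-locus --input world/loci/SYN02_L1.faa \
    --library world/library.txt --registry world/registry.tsv --out call
```

`call/type_call.tsv`:

```
status	assigned
bmc_type	SYN02
confidence	1.0000
vote_table	SYN02:10
```

All ten typed proteins in the locus vote for type SYN02, so the call is
*assigned* with confidence 10/10 = 1.  `call/assignments.tsv` lists the
per-protein best hits (first rows shown):

```
query_id	profile_name	role	bmc_type	bitscore	is_shell
SYN02_L1_g1	SYN02__SIG_periwinkle	signature_enzyme	SYN02	73.62	no
SYN02_L1_g2	SYN02__ALDDH_russet	AldDh	SYN02	58.23	no
SYN02_L1_g3		none			no
SYN02_L1_g4	SYN02__H_viridian	BMC-H	SYN02	79.05	yes
```

Gene 3 is an untyped bystander (role `none`, drawn grey in the diagram);
the others match their family's profile at 58–79 bits, far above the
20-bit acceptance threshold.  `call/closest_types.tsv` ranks reference
types by the inventory+order score:

```
rank	bmc_type	value	inventory	order	offset	orientation
1	SYN02	1.0000	1.0000	1.0000	0	forward
2	SYN01	0.0000	0.0000	0.0000	-9	forward
```

The locus matches its own type's example fingerprint exactly (S = 1 at
offset 0) and shares no components with the other types.  `call/locus.svg`
and `call/locus.html` hold the diagram and the self-contained report.

For a whole proteome, run the shell-only scan first and feed the merged
±12-gene windows back into locus analysis:

```sh
bmctyper scan-proteome --input proteome.faa --library world/library.txt \
    --out scan --call --registry world/registry.tsv
bmctyper db list --filter SPU        # browse the 68-type registry
```

Every run writes a `manifest.json` with the effective parameters and
SHA-256 input checksums; identical runs produce byte-identical artifacts.

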