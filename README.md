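# herdtyper

Herd-type classification for cattle registers: from raw animal
identification and movement records to a 17-type herd typology, the way
national veterinary-epidemiology groups need it for disease surveillance
design, risk analysis and transmission modelling.

Cattle herds differ enormously in what they do — milking, suckler
breeding, contract rearing of dairy heifers, store rearing, fattening,
dealing — and those management patterns shape how infections enter and
leave a herd. National registers record every birth, movement and
disposal per animal but carry no management labels. `herdtyper`
closes that gap:

1. **Register model** (`herdtyper.registry`) — an animal table (id, herd,
   sex, breed, parent breeds, birth date, ever-calved flag, residency
   interval) and a movement table (animal, date, source herd,
   destination herd / slaughter / export), with three snapshot dates
   (Jan 1, May 1, Sep 1) inside one study year, validation, and a
   parent-breed rule assigning each animal a dairy / beef / cross /
   other breed type (6 dairy breeds, 25 beef breeds; one parent of each
   kind makes a cross).
2. **Herd features** (`herdtyper.features`) — nine herd-level variables:
   proportions of females, dairy-bred and cross-bred animals and of
   males among the 1–2-year-olds (May snapshot); proportion ever calved
   (September); dealer throughput (purchased animals resold in under
   30 days, per out-move); and transport shares — out-moves to
   slaughter per maximum herd size, and out-/in-moves returning animals
   to their birth herd.
3. **Self-organising maps** (`herdtyper.som`) — a from-scratch Kohonen
   map (z-scored inputs, Euclidean best-matching unit, Gaussian
   neighbourhood `β = exp(−d²/2σ²)`, update
   `w ← w + α·β·(z − w)`, geometric annealing of `α` and `σ`) and a
   supervised bi-directional variant whose BMU search is driven by
   class labels early in training and by features late. Component
   planes and region histograms expose the class-discriminating
   structure used for rule extraction.
4. **Decision tree** (`herdtyper.tree`) — the extracted classifier:
   13 decisions (10 binary, 3 ternary) over the nine variables yielding
   17 herd types in six main groups, with at most 6 decisions per herd.
   The breeding (pCalvedAnimals ≥ 0.25), dairy (pDairyBreed ≥ 0.70),
   beef (pDairyBreed < 0.30) and direct-to-slaughter (pOutMovesToSL ≥
   0.5) boundaries are fixed conventions; the remaining thresholds are
   editable configuration (YAML serialization included), each with a
   sensitivity band showing how far it can move before 10% of herds
   reassign.
5. **Synthetic register generator** (`herdtyper.synth`) — real national
   registers are confidential, so a generator emits labelled registers
   in which each herd carries the management signature of one of the 17
   types (herd types: D, DnR-C, DnR-nC, DRm; BP, BSW, BSY, BSY-nR, BSB;
   M; Sdm, Sbm, Sbf, Sbmx, Rdf; F; T). Every downstream stage is tested
   against these labels.

## Worked example

The numbered scripts under `analysis/` run the full study on a
synthetic register (results land under `results/`):

```bash
python analysis/01_generate_register.py --seed 1   # register: 53094 animals
python analysis/02_compute_features.py             # nine variables per herd
python analysis/03_som_walkthrough.py  --seed 1    # staged rule extraction
python analysis/04_classify_herds.py               # tree classification
python analysis/05_report_and_sensitivity.py --seed 1
```

`03_som_walkthrough.py` prints, for seed 1:

```
stage 1 (2 variables): mean calved share
  non-breeding map region : 0.038
  rest of the map         : 0.490
stage 2 (+ pOutMovesToSL): slaughter-share histogram over the grey region
  mass below 0.5 = 70 herds (stores/rearers/traders), above = 20 (fatteners)
  antimode-suggested threshold = 0.425
```

meaning: on a supervised map trained with only the dairy-share and
calved-share variables, the unclassified non-breeding herds collect in
the region of minimal calved share (0.038 vs 0.490 elsewhere); adding
the slaughter share splits that region into two modes — herds selling
almost nothing directly to slaughter (stores, rearers, traders) and
herds selling most animals to slaughter (fatteners) — and the gap
between the modes sits near the 0.5 boundary the classifier uses.

`04_classify_herds.py` then reports 20 herds recovered in each of the
17 types (100% label recovery on 340 labelled herds), and
`05_report_and_sensitivity.py` prints the per-decision sensitivity
bands, e.g. `D4 threshold 0.60 band (0.452, 0.777)`: the calved-share
threshold separating self-rearing from non-rearing dairy herds could
move anywhere in that interval before 10% of the herds at that decision
would change class.

The same pipeline is available as a CLI
(`herdtyper generate | featurize | train-som | classify | sensitivity |
report | walkthrough`).

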