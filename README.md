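# proxlog

Simulation and analysis pipeline for **animal-borne proximity loggers** —
miniature radio transceiver tags (as deployed on breeding barn swallows)
that broadcast an ID pulse every 20 s and log periods of close proximity to
other tags as *encounters* with start/end times and min/mean/max received
signal strength (RSSI).

Raw proximity logs are messy in well-characterized ways: a five-minute
firmware cap splits long encounters, a missed pulse slot splits a log in
two, one-sided detection near the RSSI threshold yields *single* (rather
than dyadic) logs, and dying batteries produce tags that keep pulsing but
log nothing. `proxlog` gives field biologists and methods developers:

* a **discrete-event simulator** of a whole deployment — home-range
  movement around nests, a log-distance RSSI propagation model with
  orientation and body-mount effects, and a faithful tag-firmware state
  machine (detection threshold, encounter cap, memory limits, clock drift
  and receiver synchronization, battery failure);
* the **log-processing pipeline** used on real deployments — merging split
  logs, calling dyads from complementary log pairs, classifying *broken*
  and *staggered* dyads, restricting to common tag uptime;
* **reliability statistics** (reciprocal agreement of dyadic logs, a
  logistic model of dyadic-vs-single recording, broken-vs-unbroken
  comparisons) and **RSSI-thresholded contact networks**.

## The model in brief

Expected RSSI between tags at distance *d* (m) with relative antenna angle
*a*:

```
E[RSSI] = r0 + s·log10(d) + g·[body mount] − P·(1 − e^(−d/λ))·|sin a|
```

with slope *s* ≈ −23.5 per decade and reference *r0* chosen so that a
body-mounted parallel pair reads RSSI 0 at 5 m and RSSI 40 at 0.1 m — the
two thresholds used for network construction (0+ ⇒ within ~5 m;
40+ ⇒ body contact, within ~0.1 m). The orientation penalty *P* ≈ 19 RSSI
units vanishes at contact and saturates with distance; reported values are
integer-quantized and clipped to the radio's −17..57 range, with Gaussian
noise whose sd grows with distance. Firmware rules follow the deployed tag
settings: ≥0 RSSI detection threshold, 20 s pulse rate, 300 s encounter
cap, 30 concurrent encounters, 300-log memory, clock-saver restore
(`last saved + period/2 + 2 s`), 15-min receiver clock sync.

## Worked example

Simulate a small colony (8 tags, one hour), reconcile its logs, and build
networks:

```bash
python -c "import proxlog; open('run.yml','w').write(proxlog.quality_study(seed=11, n_tags=8, duration_s=3600).to_yaml())"
proxlog simulate --config run.yml --out run/
proxlog process  --logs run/logs.csv --uptime run/uptime.csv --out run/records.csv
proxlog quality  --records run/records.csv --out run/quality/
proxlog network  --records run/records.csv --thresholds 0 --thresholds 40 --out run/nets/
```

prints

```
simulated 8 tags, 509 encounter logs, 11520 receiver rows -> run
351 encounters: 137 dyadic, 214 single, 18 broken, 44 staggered
reciprocity (|a-b| per measure):
           mean_abs_diff  sd_abs_diff  min_abs_diff  max_abs_diff      t      p    n
max_rssi           7.504        7.300           0.0         39.00 -0.784  0.435  137
...
broken vs duration-matched unbroken (mean |dur diff| 7.78 s):
...
threshold 0: 28 edges, density 1.000 -> run/nets/network_rssi0.csv
threshold 40: 8 edges, density 0.286 -> run/nets/network_rssi40.csv
```

Reading this: 351 encounters were reconstructed from 509 raw logs after
merging; 39% were recorded by both tags (dyadic), the rest by one tag only
— threshold censoring at work. Broken dyads were each paired with an
unbroken dyad of similar duration (mean difference 7.78 s) to compare RSSI
levels. At the 0-RSSI threshold every tag pair interacted at least once
(density 1.0); restricting edges to body-contact encounters (RSSI ≥ 40)
keeps 8 of 28 pairs (density 0.29). The same chain is available in Python
via `proxlog.simulate_deployment`, `proxlog.process_logs`,
`proxlog.reciprocity_stats`, `proxlog.build_network`, and
`proxlog calibrate` runs the RSSI–distance calibration workflow
(mixed-model fit, distance-bin discriminability, receiver variability).

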