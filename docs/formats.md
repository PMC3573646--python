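# File formats

## mzXML (read/write)

Reading uses pyteomics and relies on the attributes that encode the
spectrum hierarchy: `scan/@msLevel`, `precursorMz` (element text),
`precursorMz/@precursorScanNum` (optional), plus base64 peak arrays
(32/64-bit, network byte order, zlib or plain). The writer emits a
minimal conforming document — flat scan list under `msRun`, 64-bit
uncompressed network-order `m/z-int` pairs — sufficient to exercise the
reader path end to end. Scan numbering is 1-based.

## Peak-tree JSON (read/write)

Lossless container for linked spectrum hierarchies:

```json
{
  "run": {
    "polarity": "+",
    "trees": [
      {
        "repetition": 0,
        "scans": [
          {"id": "1", "level": 1, "precursor_mz": null,
           "precursor_id": null, "peaks": [[308.0911, 1000000.0]]},
          {"id": "2", "level": 2, "precursor_mz": 308.0911,
           "precursor_id": "1", "peaks": [[179.0487, 50000.0]]}
        ]
      }
    ]
  }
}
```

Validation on read enforces: one root (level 1, no precursor) per tree,
`precursor_id` references an existing scan, child level = parent level
+ 1, acyclicity, `peaks` entries are `[mz, intensity]` pairs with
mz > 0 and intensity ≥ 0. Violations raise errors that name the JSON
path.

## Fragmentation-tree JSON (export/load)

`export_json` writes either a single tree
(`"type": "fragmentation_tree"`, nested `root` node records with
`efp`, `formula`, `mz`, `rel_intensity`, `ppm_error`, `ambiguous`,
`children`) or a consensus (`"type": "consensus_tree"`, map from EFP
string to `presence_fraction`, `mean_rel_intensity`,
`sd_rel_intensity`, `mean_ppm_error`, `ms_level`). Keys and children
are sorted; identical inputs produce byte-identical files.

## CML subset (export)

An XML document in the CML namespace combining the chemical and mass
spectrometric record:

- `moleculeList/molecule` — one per ion; `@id`, `@formalCharge`,
  a `formula/@concise` in the display dialect (`C5H8NO3S`), and a
  `label[@dictRef="fragtree:efp"]/@value` holding the full EFP string.
- `spectrumList/spectrum` — one per MS level (`@id` = `ms1`…`ms5`);
  each `peakList/peak` carries `@moleculeRefs` (its ion), `@xValue`
  (observed m/z, omitted for consensus entries), `@yValue` (relative
  intensity) and `@ref` pointing at the precursor ion's molecule id —
  the precursor–product link.

This subset is self-defined and documented here; full CML schema
conformance is not claimed.

## Formula serialization dialects

- `display`: CHNOPS order, count 1 omitted — `C5H8NO3S`.
- `efp_token`: CHNOPS order, all non-zero counts explicit —
  `C5H8N1O3S1`; EFP strings join tokens with `||`.

`parse_formula` inverts both.
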