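# Catalog of commercial geospatial resource indicators.
#
# Each categorical indicator lists its ordered coverage levels from WORST to
# BEST availability/precision.  `frequency` gives the number of countries (of
# 183) observed at each level in the 2017 provider coverage snapshot; the
# synthetic generator uses these as binning proportions so simulated
# categorical marginals emulate the real ones.  Numeric indicators carry a
# `direction` and a `missing_policy` instead of levels.

indicators:
  esri_geocoding:
    label: "ESRI geocoding"
    domain: geocoding
    kind: categorical
    levels:  # worst -> best
      - "Level 4"
      - "Level 3"
      - "Level 2"
      - "Level 1"
    descriptions:
      "Level 1": "address searches likely to result in either precise coordinates or interpolated location along street for address"
      "Level 2": "address searches often result in precise coordinates or interpolated location along street, but sometimes street-level coordinates or coarser"
      "Level 3": "address searches sometimes result in precise coordinates or interpolated location along street, but more often street-level coordinates or coarser"
      "Level 4": "address searches result in imprecise locations, e.g. centroids of higher-level administrative boundaries"
    frequency: {"Level 4": 74, "Level 3": 51, "Level 2": 16, "Level 1": 42}
    missing_policy: worst

  pitney_bowes_geocoding:
    label: "Pitney Bowes geocoding (highest precision available)"
    domain: geocoding
    kind: categorical
    levels:
      - "Not specified"
      - "Administrative boundaries or place-names"
      - "Post code"
      - "Street-level geocoding"
      - "Address geocoding"
      - "Precise address point geocoding"
    frequency:
      "Not specified": 1
      "Administrative boundaries or place-names": 29
      "Post code": 34
      "Street-level geocoding": 60
      "Address geocoding": 39
      "Precise address point geocoding": 20
    missing_policy: worst

  tomtom_geocoding:
    label: "TomTom geocoding (highest precision available)"
    domain: geocoding
    kind: categorical
    levels:
      - "Locality"
      - "Street-level"
      - "Interpolated address"
      - "Address point"
    frequency:
      "Locality": 44
      "Street-level": 77
      "Interpolated address": 20
      "Address point": 42
    missing_policy: worst

  mapbox_geocoding:
    label: "MapBox geocoding (highest precision available)"
    domain: geocoding
    kind: categorical
    levels:
      - "No service"
      - "Place-name"
      - "Postcode"
      - "Address geocoding"
    frequency:
      "No service": 79
      "Place-name": 60
      "Postcode": 20
      "Address geocoding": 25
    missing_policy: worst

  loqate_geocoding:
    label: "Loqate geocoding"
    domain: geocoding
    kind: categorical
    levels:
      - "Locality"
      - "Thoroughfare"
      - "Premises"
      - "Premises point"
    frequency:
      "Locality": 19
      "Thoroughfare": 68
      "Premises": 44
      "Premises point": 52
    missing_policy: worst

  esri_here_travel:
    label: "ESRI/HERE travel times"
    domain: travel
    kind: categorical
    levels:
      - "Minimal street coverage"
      - "Limited street coverage"
      - "Posted speed limits"
      - "Historical traffic"
      - "Live traffic"
      - "Predictive traffic"
    frequency:
      "Minimal street coverage": 24
      "Limited street coverage": 73
      "Posted speed limits": 15
      "Historical traffic": 20
      "Live traffic": 40
      "Predictive traffic": 11
    missing_policy: worst

  google_travel:
    label: "Google travel times (composite of five components)"
    domain: travel
    kind: composite
    # Each component is reported as good / approximate / none and scored
    # 2 / 1 / 0; the indicator is the sum over the five components (0-10).
    components:
      google_traffic:
        frequency: {good: 91, approximate: 1, none: 91}
      google_speed_limits:
        frequency: {good: 11, approximate: 166, none: 6}
      google_cycling:
        frequency: {good: 21, approximate: 0, none: 162}
      # Walking and driving direction marginals were not published at
      # component level; near-universal availability assumed (synthetic
      # generator only).
      google_walking:
        frequency: {good: 170, approximate: 10, none: 3}
      google_driving:
        frequency: {good: 175, approximate: 6, none: 2}
    missing_policy: worst

  igeolise_travel:
    label: "iGeolise TravelTime Platform"
    domain: travel
    kind: categorical
    levels:
      - "Travel times unavailable"
      - "Travel times for driving only"
      - "Travel times for public transport and driving"
    frequency:
      "Travel times unavailable": 157
      "Travel times for driving only": 3
      "Travel times for public transport and driving": 23
    missing_policy: worst

  tomtom_routing:
    label: "TomTom online routing"
    domain: travel
    kind: categorical
    levels:
      - "No online routing"
      - "Online routing without traffic"
      - "Online routing with traffic flows only"
      - "Online routing with traffic incidents and traffic flows"
    frequency:
      "No online routing": 69
      "Online routing without traffic": 57
      "Online routing with traffic flows only": 15
      "Online routing with traffic incidents and traffic flows": 42
    missing_policy: worst

  mapbox_traffic:
    label: "MapBox traffic layer"
    domain: travel
    kind: categorical
    levels:
      - "Traffic layer unavailable"
      - "Traffic layer available"
    frequency:
      "Traffic layer unavailable": 150
      "Traffic layer available": 33
    missing_policy: worst

  mb_population_per_unit:
    label: "Michael Bauer mean population per areal unit"
    domain: neighbourhood
    kind: numeric
    direction: lower_better   # smaller areal populations = finer disaggregation
    missing_policy: fallback_population
    # global median (5th; 95th centile) of the observed snapshot
    reference_quantiles: {p5: 411, p50: 130000, p95: 23801400}

  mb_attribute_groups:
    label: "Michael Bauer number of areal attribute groups"
    domain: neighbourhood
    kind: numeric
    direction: higher_better
    missing_policy: zero
    reference_quantiles: {p5: 0, p50: 4, p95: 9}

  geodemographic_availability:
    label: "Geodemographic classification / demographic data availability (Mosaic Global, CAMEO Worldwide, Maptitude)"
    domain: neighbourhood
    kind: composite
    # Count of available products, 0-3.
    components:
      mosaic_available:
        frequency: {available: 24, unavailable: 159}
      cameo_available:
        frequency: {available: 39, unavailable: 144}
      maptitude_available:
        frequency: {available: 13, unavailable: 170}
    missing_policy: zero
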