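# Default turtle-habitat zone (TZ) registry for the Pacific drift experiment.
#
# APPROXIMATE RECONSTRUCTION: these boundaries are hand-drawn approximations
# of published leatherback (Dc) and hawksbill (Ei) habitat maps, intended as
# a documented, editable default — not authoritative habitat boundaries.
# Longitudes are degrees east on 0–360; rectangles are [west, south, east,
# north] with inclusive west/south and exclusive east/north edges.
zones:
  - id: EP1
    kind: TZ
    rect: [235, -10, 270, 5]
    attributes: {species: Dc, population: Eastern, behaviour: foraging and migrating, setting: oceanic}
  - id: EP2
    kind: TZ
    rect: [240, -30, 270, -10]
    attributes: {species: Dc, population: Eastern, behaviour: foraging and migrating, setting: oceanic}
  - id: EEP
    kind: TZ
    rect: [220, 5, 268, 15]
    attributes: {species: Dc, population: Western, behaviour: foraging and migrating, setting: oceanic}
  - id: KE1
    kind: TZ
    rect: [140, 28, 160, 40]
    attributes: {species: Dc, population: Western, behaviour: foraging and migrating, setting: oceanic}
  - id: KE2
    kind: TZ
    rect: [160, 28, 185, 40]
    attributes: {species: Dc, population: Western, behaviour: foraging and migrating, setting: oceanic}
  - id: CCE
    kind: TZ
    rect: [230, 30, 245, 48]
    attributes: {species: Dc, population: Western, behaviour: foraging, setting: oceanic}
  - id: IND
    kind: TZ
    polygon: [[120, -11], [135, -11], [135, 0], [128, 2], [120, -2]]
    attributes: {species: Dc, population: Western, behaviour: nesting and foraging, setting: coastal}
  - id: PNG
    kind: TZ
    rect: [140, -12, 152, -3]
    attributes: {species: Dc, population: Western, behaviour: nesting and foraging, setting: coastal}
  - id: SB
    kind: TZ
    rect: [152, -12, 163, -5]
    attributes: {species: Dc+Ei, population: Western, behaviour: nesting and foraging, setting: coastal}
  - id: MHI
    kind: TZ
    rect: [198, 18, 206, 23]
    attributes: {species: Ei, behaviour: nesting and foraging, setting: coastal}
  - id: MX
    kind: TZ
    rect: [249, 14, 260, 24]
    attributes: {species: Dc, population: Eastern, behaviour: nesting, setting: coastal}
  - id: CR-NG
    kind: TZ
    rect: [265, 8, 270, 14]
    attributes: {species: Dc+Ei, population: Eastern, behaviour: nesting and foraging, setting: coastal}
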