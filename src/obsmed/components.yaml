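# Default 20-component OBS registry: 16 dietary + 4 lifestyle,
# 5 pro-oxidants + 15 antioxidants.  The dietary antioxidant set follows
# the commonly used OBS scheme for 24-h-recall nutrient data; edit this
# file (and keep the count invariants) to swap components.
components:
  - {name: fiber,            class: dietary,   direction: antioxidant}
  - {name: carotene,         class: dietary,   direction: antioxidant}
  - {name: riboflavin,       class: dietary,   direction: antioxidant}
  - {name: niacin,           class: dietary,   direction: antioxidant}
  - {name: vitamin_b6,       class: dietary,   direction: antioxidant}
  - {name: total_folate,     class: dietary,   direction: antioxidant}
  - {name: vitamin_b12_diet, class: dietary,   direction: antioxidant}
  - {name: vitamin_c,        class: dietary,   direction: antioxidant}
  - {name: vitamin_e,        class: dietary,   direction: antioxidant}
  - {name: calcium,          class: dietary,   direction: antioxidant}
  - {name: magnesium,        class: dietary,   direction: antioxidant}
  - {name: zinc,             class: dietary,   direction: antioxidant}
  - {name: copper,           class: dietary,   direction: antioxidant}
  - {name: selenium,         class: dietary,   direction: antioxidant}
  - {name: total_fat,        class: dietary,   direction: prooxidant}
  - {name: iron,             class: dietary,   direction: prooxidant}
  - {name: met_score,        class: lifestyle, direction: antioxidant}
  - {name: cotinine,         class: lifestyle, direction: prooxidant}
  - {name: alcohol_g_day,    class: lifestyle, direction: prooxidant, scoring: alcohol_category}
  - {name: bmi,              class: lifestyle, direction: prooxidant}
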