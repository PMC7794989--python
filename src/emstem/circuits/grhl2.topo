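Source Target Type
miR200 ZEB 2
ZEB miR200 2
ZEB ZEB 1
SNAIL ZEB 1
SNAIL miR200 2
SNAIL SNAIL 2
LIN28 let7 2
let7 LIN28 2
LIN28 LIN28 1
let7 let7 1
NFkB LIN28 1
NFkB let7 1
let7 ZEB 2
miR200 LIN28 2
GRHL2 ZEB 2
ZEB GRHL2 2
GRHL2 miR200 1
GRHL2 GRHL2 1
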