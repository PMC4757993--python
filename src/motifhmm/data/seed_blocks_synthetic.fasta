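>seed01|I
YIFADSLSDN
>seed01|III
YLFNGANDY
>seed01|V
DLVHTSETD
>seed02|I
FIFGSSLSDT
>seed02|III
FLFGGANDY
>seed02|V
DVVHPNEGG
>seed03|I
FIFAQSLTDT
>seed03|III
YLFGGANEY
>seed03|V
DLVHKNKVG
>seed04|I
FIFADSMSST
>seed04|III
WLFSNSNDY
>seed04|V
DLTHPSETG
>seed05|I
MIFGDSFSDT
>seed05|III
YLFGGAHDY
>seed05|V
DLVHPNEAS
>seed06|I
FIYNDSMSDT
>seed06|III
YLFGNGNNF
>seed06|V
DLVHPNETG
>seed07|I
FIFGESLTDT
>seed07|III
YLFGGANNY
>seed07|V
NMVHPNRTN
>seed08|I
FIFGDSLSDT
>seed08|III
YLFGGANDY
>seed08|V
QLMHPNDAG
>seed09|I
FIFNDSISDT
>seed09|III
YLFGAANDW
>seed09|V
DLTHKNEAG
>seed10|I
FIFDDSLSDT
>seed10|III
YLFNGANDF
>seed10|V
DLTHPNRVG
>seed11|I
FIWNESLSDT
>seed11|III
YLFGAANDY
>seed11|V
DLVHPSEAD
>seed12|I
FIFSDSVSDT
>seed12|III
WLFGSANDY
>seed12|V
DLVHPNEAG
>seed13|I
FIYDDSLSDN
>seed13|III
YLFGGANDF
>seed13|V
DLVHPTEAG
>seed14|I
FIFGNSLSDT
>seed14|III
YLFGATNDY
>seed14|V
DLMHPNEAD
>seed15|I
FIFNDSLSQA
>seed15|III
YLFAGSSDY
>seed15|V
DIMHPSEGG
>seed16|I
FFFADSLSDA
>seed16|III
YLFGSAHDY
>seed16|V
ELVHPNESG
>seed17|I
YIMSDSLNEA
>seed17|III
YLFGDANDY
>seed17|V
DLMHPDEAG
>seed18|I
FIFADSMSDA
>seed18|III
WLFGGANDY
>seed18|V
DLVHPTEAG
>seed19|I
FVFNDSISDT
>seed19|III
YIFNNGNDY
>seed19|V
DLVHPTDAG
>seed20|I
FIFGDSLSDN
>seed20|III
HLFGGANDY
>seed20|V
DLVHPDEAG
>seed21|I
FIFSDSLSDN
>seed21|III
HVFGDGNDY
>seed21|V
DLVHPNESG
>seed22|I
FIFGDSLNDV
>seed22|III
YLFGGANDY
>seed22|V
DLVHPSEAN
>seed23|I
FIYSESVSET
>seed23|III
YVFGGSNDY
>seed23|V
DLVHPNEVG
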