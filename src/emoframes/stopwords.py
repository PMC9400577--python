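"""Italian function-word list used to flag non-content tokens.

Used only when no part-of-speech tags are available (the annotated synthetic
corpora carry POS arrays, and a real parser plug-in would too).  The list
covers articles, prepositions (simple and articulated), pronouns, common
auxiliaries/copulas, conjunctions and high-frequency adverbs/determiners.
Matching happens on surface forms, before stemming.
"""

ITALIAN_STOPWORDS = frozenset("""
a ad al allo ai agli all agl alla alle con col coi da dal dallo dai dagli
dall dagl dalla dalle di del dello dei degli dell degl della delle in nel
nello nei negli nell negl nella nelle su sul sullo sui sugli sull sugl sulla
sulle per tra fra contro io tu lui lei noi voi loro mio mia miei mie tuo tua
tuoi tue suo sua suoi sue nostro nostra nostri nostre vostro vostra vostri
vostre mi ti ci vi lo la li le gli ne il un uno una ma ed se perche perché
anche come dov dove che chi cui non piu più quale quanto quanti quanta
quante quello quelli quella quelle questo questi questa queste si tutto
tutti tutte a l un' all' dall' dell' nell' sull' e o ovvero oppure cioè cioe
essere sono sei è e' sei siamo siete sia siano sarò sarà saranno sarei
sarebbe ero eri era eravamo eravate erano fui fosti fu fummo foste furono
fossi fosse fossimo fossero essendo stato stata stati state avere ho hai ha
abbiamo avete hanno abbia abbiano avrò avrà avranno avrei avrebbe avevo
avevi aveva avevamo avevate avevano ebbi avesti ebbe avemmo aveste ebbero
avessi avesse avessimo avessero avendo avuto avuta avuti avute fare faccio
fai fa facciamo fate fanno stare sto stai sta stiamo state stanno questo qui
qua là li' già ancora sempre mai poi dopo prima ora adesso allora quindi
dunque però pero infatti inoltre invece mentre quando senza sotto sopra
verso presso durante tramite ogni alcuni alcune alcuna alcuno nessuno
nessuna qualche qualsiasi altro altra altri altre stesso stessa stessi
stesse tale tali cosa cose modo solo soltanto molto molti molta molte poco
pochi poca poche troppo tanto tanti tanta tante meno davvero circa ecco
""".split())
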